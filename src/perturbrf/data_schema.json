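{
  "format": "perturbrf-hdf5",
  "version": 1,
  "notes": "Complex fields are stored as paired float64 re/im datasets. Voxel arrays are (nx, ny, nz); edge/face fields are (3, nx, ny, nz) with component-major layout and x fastest within a component. All grid metadata lives in attributes on the carrying group.",
  "grid_attributes": {
    "resolution_m": "float64[3] voxel edge lengths (dx, dy, dz) in meters",
    "frequency_hz": "float64 operating frequency in Hz",
    "origin_m": "float64[3] physical coordinate of the (0,0,0) voxel corner",
    "format_version": "int, currently 1",
    "package_version": "string"
  },
  "groups": {
    "/materials": {
      "datasets": {
        "sigma": "float64 (nx,ny,nz) conductivity S/m",
        "eps_r": "float64 (nx,ny,nz) relative permittivity",
        "rho_m": "float64 (nx,ny,nz) mass density kg/m^3"
      }
    },
    "/fields": {
      "datasets": {
        "E_re": "float64 (3,nx,ny,nz) edge E-field, real part V/m",
        "E_im": "float64 (3,nx,ny,nz) edge E-field, imaginary part V/m",
        "H_re": "float64 (3,nx,ny,nz) face H-field, real part A/m (optional)",
        "H_im": "float64 (3,nx,ny,nz) face H-field, imaginary part A/m (optional)"
      }
    },
    "/solver": {
      "datasets": {"residuals": "float64 per-iteration relative residuals (optional)"},
      "attributes": {
        "provenance": "JSON string: config hash, seed, tolerances, margins"
      }
    },
    "/sar": {
      "datasets": {
        "values": "float64 (nx,ny,nz) SAR W/kg",
        "mip_x | mip_y | mip_z": "float64 2D maximum-intensity projections (optional)"
      },
      "attributes": {"averaged_mass_g": "float64, 0 for local SAR"}
    }
  }
}
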