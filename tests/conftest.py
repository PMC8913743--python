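"""Shared heavy fixtures: the standard validation phantom and its solves.

The full-domain factorizations and the perturbation pipeline runs are the
expensive parts of the suite, so they are computed once per session and
shared between the oracle-equivalence, SAR and margin tests.
"""

import pytest

import perturbrf as prf


@pytest.fixture(scope="session")
def standard_setup():
    return prf.standard_test_phantom()


@pytest.fixture(scope="session")
def standard_reference(standard_setup):
    """Brute-force full-domain solves without and with the implant."""
    s = standard_setup
    grid, mat, q = s["grid"], s["materials"], s["q"]
    metal = s["implant_material"]
    op_bg = prf.assemble(grid, mat)
    E_bg, H_bg = prf.solve_full(op_bg, q)
    del op_bg
    mat_imp = mat.with_implant(s["implant_mask"], metal.sigma, metal.eps_r, metal.rho_m)
    op_imp = prf.assemble(grid, mat_imp)
    E_imp, H_imp = prf.solve_full(op_imp, q)
    del op_imp
    return {"E_bg": E_bg, "H_bg": H_bg, "E_imp": E_imp, "H_imp": H_imp, "mat_imp": mat_imp}


@pytest.fixture(scope="session")
def standard_pipeline(standard_setup, standard_reference):
    """Matrix-free perturbation runs of the standard phantom, margins 2/4/8."""
    s = standard_setup
    metal = s["implant_material"]
    out = {}
    for margin in (2, 4, 8, 12):
        config = prf.SolverConfig(fft_margin_voxels=margin)
        problem = prf.make_problem(
            s["materials"], s["implant_mask"], metal.sigma, metal.eps_r,
            standard_reference["E_bg"], s["grid"], config,
        )
        solution = prf.solve_perturbation(
            problem, reconstruct_h=True, H_bg=standard_reference["H_bg"]
        )
        out[margin] = {"problem": problem, "solution": solution}
    return out
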