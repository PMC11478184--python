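"""Shared fixtures: toy promoter sets, a small synthetic study, and the
OLS identity checks applied to every fit the tests produce."""

from __future__ import annotations

import numpy as np
import pytest

from corepromoter import (
    PromoterRecord,
    PromoterSet,
    SyntheticSpec,
    Window,
    build_pfm,
    generate_promoter_set,
    pfm_to_ppm,
    pick_reference,
    ppm_to_pssm,
)


@pytest.fixture
def toy_window() -> Window:
    return Window(-1, 1)


@pytest.fixture
def toy_promoters(toy_window: Window) -> PromoterSet:
    """Four 3-mers with an easily hand-talliable composition."""
    return PromoterSet(
        toy_window,
        [
            PromoterRecord("p1", "ACG"),
            PromoterRecord("p2", "ACG"),
            PromoterRecord("p3", "ATG"),
            PromoterRecord("p4", "GCG"),
        ],
    )


@pytest.fixture(scope="session")
def small_study():
    """A seeded synthetic population with its PSSM and reference id.

    500 background windows keep matrix estimates stable while staying
    fast; pseudocount 1 guarantees a finite matrix.
    """
    spec = SyntheticSpec(n_sequences=500, seed=11)
    promoters = generate_promoter_set(spec)
    pssm = ppm_to_pssm(pfm_to_ppm(build_pfm(promoters), pseudocount=1.0))
    reference_id = pick_reference(pssm, promoters)
    return spec, promoters, pssm, reference_id


def assert_ols_identities(fit, rtol: float = 1e-6) -> None:
    """Algebraic facts every intercept-OLS fit must satisfy."""
    resid = np.array([r for _, r in fit.residuals])
    scale = max(float(np.abs(resid).sum()), 1.0)
    assert abs(resid.sum()) <= rtol * scale
    assert abs(fit.residual_slope) <= 1e-6
    if not fit.perfect:
        assert fit.F == pytest.approx(fit.t_C1**2, rel=rtol)
        assert fit.adj_r2 <= fit.r2 + 1e-12
        assert 0.0 <= fit.r2 <= 1.0 + 1e-12
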