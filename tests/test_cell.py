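"""Cell-model arithmetic, conservation and assembly checks."""

import numpy as np
import pytest

from mitoros.cell import (
    CellState,
    PRESETS,
    Workload,
    build_cell_model,
    cell_initial,
    run_insitu_scenario,
    tissue_uptake_estimate,
)


def test_uptake_estimate_single_clearance():
    per, _ = tissue_uptake_estimate(20.0, 0.5, 0.015, 5.0)
    assert per == pytest.approx(10.0)  # nmol per mL of tissue


def test_uptake_estimate_sustained_stimulation():
    _, total = tissue_uptake_estimate(20.0, 0.5, 0.015, 5.0)
    assert total == pytest.approx(10.0 * (5.0 / 0.015) / 1000.0)
    assert total > 3.0  # more than 3 umol per mL over 5 s


def test_uptake_estimate_duration_equals_clearance():
    per, total = tissue_uptake_estimate(20.0, 0.5, 0.015, 0.015)
    assert total == pytest.approx(per / 1000.0)


def test_uptake_estimate_rejects_nonpositive_inputs():
    with pytest.raises(ValueError):
        tissue_uptake_estimate(0.0, 0.5, 0.015, 5.0)


def test_presets_match_printed_workloads():
    assert PRESETS["glu"] == Workload(1.0, 1.0)
    assert PRESETS["GLU"] == Workload(3.0, 1.0)
    assert PRESETS["work"] == Workload(3.0, 10.0)
    with pytest.raises(ValueError):
        Workload(-1.0, 1.0)


def test_unknown_preset_rejected():
    with pytest.raises(ValueError, match="unknown preset"):
        run_insitu_scenario("hyperGLU")


def test_cellstate_rejects_negative_amounts():
    with pytest.raises(ValueError):
        CellState(atp=-1.0)


def test_adenine_and_transporter_conserved_in_rhs():
    """ATP production and consumption close exactly: the adenine, NAD(H)
    and transporter totals have identically zero net rate at any state."""
    m = build_cell_model()
    x = cell_initial(m)
    rng = np.random.default_rng(11)
    for _ in range(5):
        y = x * rng.uniform(0.5, 1.5, x.size)
        dx = m.rhs(0.0, y)
        for pair in (("atp", "adp"), ("nadh_c", "nad_c"), ("t_out", "t_in")):
            i = [m.pool_slice.start + m.pool_index[p] for p in pair]
            assert abs(dx[i[0]] + dx[i[1]]) < 1e-12 * max(abs(dx[i[0]]), 1.0)


def test_atp_rate_matches_independent_flux_sum():
    """The ATP row of the model equals the sum of its named fluxes
    (glycolysis + synthase - ATPase - Na/K pump), re-derived by hand."""
    m = build_cell_model()
    x = cell_initial(m)
    pools = m.pools_dict(x)
    for name, v in m.clamped.items():
        pools[name] = v
    psi = m.psi(x)
    total = 0.0
    for flux in m.customs:
        if "atp" in flux.stoich:
            total += flux.stoich["atp"] * flux.rate(pools, psi, m.rates,
                                                    m.params)
    atp_row = m.rhs(0.0, x)[m.pool_slice.start + m.pool_index["atp"]]
    assert atp_row == pytest.approx(total, rel=1e-12, abs=1e-15)
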