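"""Equilibria and eigenvalue spectra against independent closed forms.

The analytic eigenvalue expressions asserted here are encoded only in this
test module; the implementation computes spectra numerically from
complex-step Jacobians.
"""

import numpy as np
import pytest

from iadtmodels import (
    classify, default_params, eigen_analysis, find_equilibria, get_model,
    simulate, TreatmentSchedule,
)

N_DRAWS = 20


# ---------------------------------------------------------------------------
# random valid parameter draws per model
# ---------------------------------------------------------------------------

def draw_i08(rng, model_b=False):
    d = dict(
        gamma_D_max=rng.uniform(0.1, 1.0), delta_D_max=rng.uniform(0.1, 1.0),
        gamma_DA=rng.uniform(0.05, 0.95), delta_DA=rng.uniform(0.1, 3.0),
        k_DA_gamma=rng.uniform(0.5, 5.0), k_DA_delta=rng.uniform(0.5, 5.0),
        mu_DI_max=rng.uniform(0.0, 0.02), c_A0=rng.uniform(5.0, 20.0),
        delta_cA=rng.uniform(0.01, 0.3), w_D=1.0, w_I=1.0,
    )
    if model_b:
        d["delta_IA"] = rng.uniform(0.1, 2.0)
        d["gamma_IA"] = rng.uniform(0.1, 2.0)
    return d


def draw_h10(rng):
    md = get_model("H10")
    d = md.pdict(default_params("H10"))
    for k in md.param_names:
        if k.startswith("mu_"):
            d[k] = rng.uniform(0.0, 0.2)
        elif k.startswith("gamma_"):
            d[k] = rng.uniform(-1.0, 1.0)
    return d


def draw_p12a(rng):
    d = get_model("P12A").pdict(default_params("P12A"))
    for k in d:
        d[k] *= rng.uniform(0.5, 2.0)
    d["q_min"] = min(d["q_min"], 0.8 * d["q_max"])
    return d


def draw_b16a(rng):
    d = get_model("B16A").pdict(default_params("B16A"))
    for k in d:
        d[k] *= rng.uniform(0.5, 2.0)
    d["q_min"] = min(d["q_min"], 0.5 * d["q_max"])
    return d


def draw_z17(rng):
    a21 = rng.uniform(0.05, 0.3)
    a31 = rng.uniform(a21 + 0.05, 0.6)
    a32 = rng.uniform(a31 + 0.05, 0.95)
    a12 = rng.uniform(0.04, a32 - 0.01)
    a23 = rng.uniform(0.05, 0.5)
    a13 = rng.uniform(max(a23, a21) + 0.05, 0.98)
    return dict(
        gamma_D=rng.uniform(0.01, 0.1), gamma_P=rng.uniform(0.01, 0.1),
        gamma_I=rng.uniform(0.01, 0.1), K_P=rng.uniform(5.0, 20.0),
        K_I=rng.uniform(5.0, 20.0), beta=rng.uniform(0.2, 0.9),
        delta=rng.uniform(0.02, 0.2), alpha_12=a12, alpha_13=a13,
        alpha_21=a21, alpha_23=a23, alpha_31=a31, alpha_32=a32,
    )


def draw_b20(rng):
    return dict(p_S=rng.uniform(0.05, 0.9), delta_D=rng.uniform(0.01, 0.5),
                gamma_PSA=rng.uniform(0.02, 0.5),
                delta_PSA=rng.uniform(0.02, 0.5))


def _spectrum(model_id, d, phase, which=0):
    md = get_model(model_id)
    p = md.pvector(d)
    eqs = find_equilibria(model_id, p, phase, include_numeric=False)
    return eigen_analysis(model_id, p, eqs[which]).eigenvalues


def _match(numeric, expected, rtol=1e-7):
    """Each expected eigenvalue appears in the numeric spectrum."""
    numeric = np.asarray(numeric, complex)
    for lam in np.atleast_1d(expected):
        err = np.min(np.abs(numeric - lam))
        assert err <= rtol * max(1.0, abs(lam)), (lam, numeric)


# ---------------------------------------------------------------------------
# catalogue contents
# ---------------------------------------------------------------------------

class TestEquilibriumCatalogue:
    def test_h10_origin_is_unique(self, rng):
        md = get_model("H10")
        for phase in ("on", "off"):
            eqs = find_equilibria("H10", md.pvector(draw_h10(rng)), phase,
                                  seed=3)
            assert len(eqs) == 1
            assert np.allclose(eqs[0].state, 0.0, atol=1e-8)

    def test_z17_off_contains_producer_only_point(self):
        p = default_params("Z17")
        d = get_model("Z17").pdict(p)
        eqs = find_equilibria("Z17", p, "off", include_numeric=False)
        target = np.array([0.0, d["K_P"], 0.0, d["K_P"] / d["delta"]])
        assert any(np.allclose(e.state, target, rtol=1e-10) for e in eqs)

    def test_e16_has_no_equilibria(self):
        assert find_equilibria("E16", default_params("E16"), "off",
                               include_numeric=False) == []

    def test_zero_rhs_contract(self, rng):
        for mid, drawer in (("I08A", draw_i08), ("P12A", draw_p12a),
                            ("B16A", draw_b16a), ("Z17", draw_z17),
                            ("B20", draw_b20)):
            md = get_model(mid)
            p = md.pvector(drawer(rng))
            for phase in ("on", "off"):
                for eq in find_equilibria(mid, p, phase,
                                          include_numeric=False):
                    if np.any(np.isnan(eq.state)):
                        continue
                    assert eq.residual(p) <= 1e-10

    def test_stable_equilibrium_is_persistent(self):
        """Simulation started at a stable rest point stays there for 10^3
        days."""
        p = default_params("B16A")
        eqs = find_equilibria("B16A", p, "off", include_numeric=False)
        reports = [eigen_analysis("B16A", p, e) for e in eqs]
        stable = [r for r in reports if r.classification == "stable"]
        assert stable
        x0 = stable[0].equilibrium.state
        sched = TreatmentSchedule((), 0.0, 1000.0)
        traj = simulate("B16A", p, x0, sched, np.linspace(0, 1000, 20))
        assert np.max(np.abs(traj.states - x0[:, None])) < 1e-6


# ---------------------------------------------------------------------------
# eigenvalue oracles
# ---------------------------------------------------------------------------

class TestEigenOracles:
    def test_i08a_line_spectrum(self, rng):
        for _ in range(N_DRAWS):
            d = draw_i08(rng)
            for phase, u in (("on", 1), ("off", 0)):
                ev = _spectrum("I08A", d, phase)
                _match(ev, 0.0, rtol=1e-9)
                _match(ev, -d["delta_cA"])
                cA = d["c_A0"] * (1 - u)
                gamma_D = d["gamma_D_max"] * (
                    d["gamma_DA"] + (1 - d["gamma_DA"]) * cA
                    / (cA + d["k_DA_gamma"]))
                delta_D = d["delta_D_max"] * (
                    d["delta_DA"] + (1 - d["delta_DA"]) * cA
                    / (cA + d["k_DA_delta"]))
                mu = d["mu_DI_max"] * (1 - cA / d["c_A0"])
                _match(ev, gamma_D - delta_D - mu)

    def test_i08a_lambda3_off_printed_form(self, rng):
        for _ in range(N_DRAWS):
            d = draw_i08(rng)
            lam3 = (d["gamma_D_max"]
                    + (d["gamma_DA"] - 1) * d["gamma_D_max"] * d["k_DA_gamma"]
                    / (d["c_A0"] + d["k_DA_gamma"])
                    - d["delta_D_max"]
                    - (d["delta_DA"] - 1) * d["delta_D_max"] * d["k_DA_delta"]
                    / (d["c_A0"] + d["k_DA_delta"]))
            _match(_spectrum("I08A", d, "off"), lam3)

    def test_i08b_independent_channel_eigenvalue(self, rng):
        for _ in range(N_DRAWS):
            d = draw_i08(rng, model_b=True)
            for phase, u in (("on", 1), ("off", 0)):
                lam1 = (u - 1) * (d["gamma_IA"] - d["delta_IA"]) \
                    / d["gamma_IA"]
                _match(_spectrum("I08B", d, phase), lam1)

    def test_h10_origin_spectrum(self, rng):
        for _ in range(N_DRAWS):
            d = draw_h10(rng)
            for phase, u in (("on", 1), ("off", 0)):
                lam1 = d["gamma_Irr_off"] + u * (d["gamma_Irr_on"]
                                                 - d["gamma_Irr_off"])
                a = d["gamma_D_off"] + d["gamma_I_off"]
                b = d["gamma_D_on"] + d["gamma_I_on"]
                c = d["gamma_D_off"] - d["gamma_I_off"]
                dd = d["gamma_D_on"] - d["gamma_I_on"]
                disc2 = c ** 2 + u * (
                    u * ((c - dd) ** 2 - 4 * d["mu_DI"] * d["mu_ID"])
                    - 2 * c * (c - dd) + 4 * d["mu_DI"] * d["mu_ID"])
                disc = np.sqrt(complex(disc2))
                lam23 = [0.5 * (u * (b - a) + a + disc),
                         0.5 * (u * (b - a) + a - disc)]
                _match(_spectrum("H10", d, phase), [lam1] + lam23)

    def test_p12a_quota_eigenvalue_on_off(self, rng):
        for _ in range(N_DRAWS):
            d = draw_p12a(rng)
            lam_on = -(d["gamma_max"] + d["delta_q"])
            lam_off = lam_on - d["v_max"] / ((d["k_q2"] + 1)
                                             * (d["q_max"] - d["q_min"]))
            _match(_spectrum("P12A", d, "on"), lam_on)
            _match(_spectrum("P12A", d, "off"), lam_off)

    def test_p12a_off_quota_node_always_attracting_in_q(self, rng):
        """The quota direction at the off-treatment rest point is always a
        stable node over randomized valid parameters."""
        for _ in range(100):
            d = draw_p12a(rng)
            lam_off = -(d["gamma_max"] + d["delta_q"]) \
                - d["v_max"] / ((d["k_q2"] + 1) * (d["q_max"] - d["q_min"]))
            assert lam_off < 0
            _match(_spectrum("P12A", d, "off"), lam_off)

    def test_b16a_interior_point_spectrum(self, rng):
        for _ in range(N_DRAWS):
            d = draw_b16a(rng)
            for phase, u in (("on", 1), ("off", 0)):
                gamma = d["gamma_1"] * u + d["gamma_2"]
                q_eq = d["q_max"] + d["gamma_max"] * (d["q_min"] - d["q_max"]) \
                    / (d["gamma_max"] + gamma)
                lams = [d["gamma_max"] * (d["q_min"] / q_eq - 1.0),
                        -d["delta_PSA"], -d["tau_delta"],
                        -d["gamma_max"] - gamma]
                _match(_spectrum("B16A", d, phase, which=1), lams)

    def test_z17_interior_off_spectrum(self, rng):
        for _ in range(N_DRAWS):
            d = draw_z17(rng)
            a = 1 + d["beta"]
            b = d["beta"] - d["alpha_12"] + 1
            dn = d["alpha_21"] * b + 1
            e = d["beta"] + d["alpha_21"] * b ** 2 - d["alpha_12"] + 1
            disc = np.sqrt(complex(
                (e * d["gamma_D"] + d["beta"] * d["gamma_P"]
                 + d["gamma_P"]) ** 2
                - 4 * a * dn * e * d["gamma_D"] * d["gamma_P"]))
            lams = [-d["delta"],
                    d["gamma_I"] - d["gamma_I"] * d["K_P"]
                    * (b * d["alpha_31"] + d["alpha_32"]) / (dn * d["K_I"]),
                    -(a * d["gamma_P"] + disc + e * d["gamma_D"]) / (2 * a * dn),
                    (disc - a * d["gamma_P"] - e * d["gamma_D"]) / (2 * a * dn)]
            _match(_spectrum("Z17", d, "off", which=1), lams)

    def test_b20_off_plane_double_zero(self, rng):
        for _ in range(N_DRAWS):
            d = draw_b20(rng)
            ev = _spectrum("B20", d, "off")
            assert abs(ev[0]) <= 1e-9 and abs(ev[1]) <= 1e-9
            _match(ev, -d["delta_PSA"])


class TestClassify:
    @pytest.mark.parametrize("eigs, expected", [
        ((-1.0, -2.0, -3.0), "stable"),
        ((0.0, 0.0, -0.12), "nonhyperbolic"),
        ((0.1, -0.2), "saddle"),
        ((0.3, 0.1), "unstable"),
        ((1e-12, -1.0), "nonhyperbolic"),
    ])
    def test_examples(self, eigs, expected):
        assert classify(eigs) == expected

    def test_invalid_spectra(self):
        with pytest.raises(ValueError):
            classify([])
        with pytest.raises(ValueError):
            classify([np.nan])

    def test_h10_stable_on_unstable_off(self):
        """Net decay on-treatment and net growth off-treatment classify the
        origin as stable and unstable, respectively."""
        md = get_model("H10")
        d = md.pdict(default_params("H10"))
        d.update(gamma_D_on=-0.05, gamma_I_on=-0.01, gamma_Irr_on=-0.004,
                 gamma_D_off=0.03, gamma_I_off=0.01, gamma_Irr_off=0.004)
        p = md.pvector(d)
        on = eigen_analysis("H10", p, find_equilibria("H10", p, "on",
                                                      include_numeric=False)[0])
        off = eigen_analysis("H10", p, find_equilibria("H10", p, "off",
                                                       include_numeric=False)[0])
        assert on.classification == "stable"
        assert off.classification == "unstable"
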