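"""Unit and property tests of the daily food-web update rules."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from streamweb import (
    FoodWebState,
    InvalidParameterError,
    ModelParams,
    UncalibratedParameterError,
    emergence_flux,
    simulate,
    step,
    type3_fraction,
)
from streamweb.model import algae_step, detritus_step, predation_on_armored, \
    predation_on_vulnerable


# ---------------------------------------------------------------- oracle
def naive_step(pools: dict, p: ModelParams, trout=True, sal=True) -> dict:
    """Straight-line reimplementation of one daily update.

    Written independently of the package internals: every flow is
    spelled out pool by pool, with the same proportional-rescaling rule
    when a pool would be overdrawn.
    """
    f3 = lambda B, a: B * B / (a * a + B * B)
    A, D = pools["A"], pools["D"]
    Ha, Hd, Ga, Gd = (pools["H_alg"], pools["H_det"],
                      pools["G_alg"], pools["G_det"])
    T = pools["T"] if trout else 0.0
    S = pools["S"] if sal else 0.0
    H, G = Ha + Hd, Ga + Gd

    # basal pools
    a_gain = p.b_a * (1 - p.L) * A
    graze = p.c_alg * (Ha + Ga) * A
    a_scale = min(1.0, (A + a_gain) / graze) if graze > 0 else 1.0
    new_A = A + a_gain - graze * a_scale if graze * a_scale < A + a_gain else 0.0
    d_cons = p.c_det * (Hd + Gd) * D
    d_scale = min(1.0, (D + p.I) / d_cons) if d_cons > 0 else 1.0
    new_D = D + p.I - d_cons * d_scale if d_cons * d_scale < D + p.I else 0.0

    # predation demands
    phi = f3(H, p.alpha) if H > 0 else 0.0
    tr_d = p.c_t * T * phi
    sv_d = p.c_s * S * phi
    psi = f3(G, p.alpha) if G > 0 else 0.0
    if p.armored_response == "scaled":
        sa_d = p.armored_cap * p.c_s * S * psi
    else:
        sa_d = min(p.armored_cap * p.c_s * S, p.c_s * S * psi)

    intakes = {"tr": 0.0, "sv": 0.0, "sa": 0.0}
    emerged = 0.0

    def consumer(pool, b, c, R, r_scale, preds):
        nonlocal emerged
        growth = b * c * pool * R * r_scale
        losses = [d for _, d in preds] + [p.e_h * pool, p.m_h * pool]
        tot = sum(losses)
        scale = 1.0
        if tot > pool + growth and tot > 0:
            scale = (pool + growth) / tot
        for (key, d) in preds:
            intakes[key] += d * scale
        emerged += p.e_h * pool * scale
        new = pool + growth - tot * scale
        return 0.0 if tot > pool + growth else new

    share_a = Ha / H if H > 0 else 0.0
    new_Ha = consumer(Ha, p.b_alg, p.c_alg, A, a_scale,
                      [("tr", tr_d * share_a), ("sv", sv_d * share_a)])
    new_Hd = consumer(Hd, p.b_det, p.c_det, D, d_scale,
                      [("tr", tr_d * (1 - share_a) if H > 0 else 0.0),
                       ("sv", sv_d * (1 - share_a) if H > 0 else 0.0)])
    ga_share = Ga / G if G > 0 else 0.0
    new_Ga = consumer(Ga, p.b_alg, p.c_alg, A, a_scale,
                      [("sa", sa_d * ga_share)])
    new_Gd = consumer(Gd, p.b_det, p.c_det, D, d_scale,
                      [("sa", sa_d * (1 - ga_share) if G > 0 else 0.0)])

    tr_terr = min(p.c_t * T, p.X)
    sa_terr = min(p.c_s * S, max(0.0, p.X - p.c_t * T))
    new_T = pools["T"] + p.b_t * (intakes["tr"] + tr_terr)
    new_S = pools["S"] + p.b_s * (intakes["sv"] + intakes["sa"] + sa_terr)
    return {"A": new_A, "D": new_D, "H_alg": new_Ha, "H_det": new_Hd,
            "G_alg": new_Ga, "G_det": new_Gd, "T": new_T, "S": new_S,
            "emergence": emerged}


# ------------------------------------------------------- functional form
@pytest.mark.parametrize("B,alpha,expected", [
    (0.0, 1.0, 0.0),          # no prey, no feeding
    (2.0, 2.0, 0.5),          # half-saturation by definition
    (3.0, 1.0, 0.9),          # 9 / (1 + 9)
])
def test_type3_fraction_values(B, alpha, expected):
    assert type3_fraction(B, alpha) == pytest.approx(expected, abs=1e-15)


def test_type3_fraction_shape():
    """Sigmoid: strictly increasing, inflection below alpha, bounded by 1."""
    alpha = 0.7
    xs = [0.01 * i for i in range(1, 300)]
    ys = [type3_fraction(x, alpha) for x in xs]
    assert all(b > a for a, b in zip(ys, ys[1:]))
    assert all(0 <= y < 1 for y in ys)
    # second difference changes sign below alpha (inflection at alpha/sqrt(3))
    d2 = [ys[i + 1] - 2 * ys[i] + ys[i - 1] for i in range(1, len(ys) - 1)]
    flip = next(i for i in range(len(d2) - 1) if d2[i] > 0 > d2[i + 1])
    assert xs[flip + 1] < alpha


def test_type3_fraction_invalid_alpha():
    with pytest.raises(InvalidParameterError):
        type3_fraction(1.0, 0.0)
    with pytest.raises(InvalidParameterError):
        type3_fraction(1.0, -2.0)


# ------------------------------------------------------------ basal pools
def test_algae_step_examples(params):
    s = FoodWebState(A=1.59, D=10, H_alg=0.0, H_det=0.0, G_alg=0.0,
                     G_det=0.0, T=0, S=0)
    gain, loss = algae_step(s, params)
    assert gain == pytest.approx(0.15 * 0.10 * 1.59, abs=1e-12)
    assert loss == 0.0
    s2 = s.replace(H_alg=0.05, G_alg=0.065)
    _, loss2 = algae_step(s2, params)
    assert loss2 == pytest.approx(0.2 * 0.115 * 1.59, abs=1e-12)
    s0 = s.replace(A=0.0)
    assert algae_step(s0, params) == (0.0, 0.0)


def test_detritus_step_examples(params):
    s = FoodWebState(A=1.0, D=10.0, H_alg=0, H_det=0.05, G_alg=0,
                     G_det=0.065, T=0, S=0)
    inp, cons = detritus_step(s, params)
    assert inp == 1.7
    assert cons == pytest.approx(0.35 * 0.115 * 10, abs=1e-12)
    assert detritus_step(s.replace(D=0.0), params)[1] == 0.0


# -------------------------------------------------------------- predation
def test_vulnerable_predation_split_at_half_saturation(params):
    """At H = alpha the trout takes c_t·T/2, split by biomass share."""
    h = params.alpha / 2
    s = FoodWebState(A=1, D=1, H_alg=h, H_det=h, G_alg=0, G_det=0,
                     T=5.12, S=0)
    losses = predation_on_vulnerable(s, params)
    assert losses["trout_H_alg"] + losses["trout_H_det"] == \
        pytest.approx(0.075 * 5.12 * 0.5, rel=1e-12)
    assert losses["trout_H_alg"] == pytest.approx(losses["trout_H_det"])
    assert losses["salamander_H_alg"] == 0.0


def test_vulnerable_predation_zero_cases(params):
    empty = FoodWebState(A=1, D=1, H_alg=0, H_det=0, G_alg=0.1, G_det=0,
                         T=5, S=5)
    assert all(v == 0 for v in predation_on_vulnerable(empty, params).values())
    no_pred = FoodWebState(A=1, D=1, H_alg=0.1, H_det=0.1, G_alg=0,
                           G_det=0, T=0, S=0)
    assert all(v == 0 for v in predation_on_vulnerable(no_pred, params).values())


def test_armored_cap_binds_under_hard_cap_mode(params):
    """With G >> alpha the hard cap pins intake at 6.5% of c_s·S."""
    p = params.replace(armored_response="cap")
    s = FoodWebState(A=1, D=1, H_alg=0, H_det=0, G_alg=50.0, G_det=50.0,
                     T=0, S=13.42)
    losses = predation_on_armored(s, p)
    total = sum(losses.values())
    assert total == pytest.approx(0.065 * 0.02236 * 13.42, rel=1e-12)


def test_armored_scaled_mode_tracks_functional_response(params):
    """Scaled mode: intake is 6.5% of the type III demand at any G."""
    s = FoodWebState(A=1, D=1, H_alg=0, H_det=0, G_alg=0.3, G_det=0.4,
                     T=0, S=13.42)
    psi = type3_fraction(0.7, params.alpha)
    total = sum(predation_on_armored(s, params).values())
    assert total == pytest.approx(0.065 * 0.02236 * 13.42 * psi, rel=1e-12)
    zero = s.replace(S=0.0)
    assert sum(predation_on_armored(zero, params).values()) == 0.0


# ----------------------------------------------------- emergence & predators
def test_emergence_flux_reference_stock(params):
    s = FoodWebState(A=1, D=1, H_alg=0.05, H_det=0.05, G_alg=0.065,
                     G_det=0.065, T=0, S=0)
    assert emergence_flux(s, params) == pytest.approx(0.039 * 0.23, abs=1e-15)
    assert emergence_flux(s.replace(H_alg=0, H_det=0, G_alg=0, G_det=0),
                          params) == 0.0


@pytest.mark.parametrize("T,X,expected_terr", [
    (5.12, 0.261, 0.261),   # demand 0.384 exceeds the donor flux
    (8.0, 0.261, 0.261),
    (1.0, 0.261, 0.075),    # demand below the flux
])
def test_trout_terrestrial_intake_capped_at_input(params, T, X, expected_terr):
    p = params.replace(X=X)
    s = FoodWebState(A=1, D=1, H_alg=0, H_det=0, G_alg=0, G_det=0, T=T, S=0)
    _, ledger = step(s, p)
    assert ledger["trout_terrestrial_intake"] == pytest.approx(expected_terr)


@pytest.mark.parametrize("T,X,S,expected", [
    (5.12, 0.261, 13.42, 0.0),                    # trout exhaust the flux
    (5.12, 0.522, 13.42, 0.522 - 0.075 * 5.12),   # leftover below demand
    (0.0, 0.261, 13.42, 0.261),                   # no trout: full flux offered
])
def test_salamander_gets_only_leftover_subsidy(params, T, X, S, expected):
    p = params.replace(X=X)
    s = FoodWebState(A=1, D=1, H_alg=0, H_det=0, G_alg=0, G_det=0, T=T, S=S)
    _, ledger = step(s, p)
    assert ledger["salamander_terrestrial_intake"] == \
        pytest.approx(min(expected, 0.02236 * S), abs=1e-12)


def test_invertebrate_balance_point(params):
    """When b·c·R equals e_h + m_h the pool is exactly stationary."""
    R = (params.e_h + params.m_h) / (params.b_alg * params.c_alg)
    s = FoodWebState(A=R, D=0, H_alg=0.05, H_det=0, G_alg=0, G_det=0,
                     T=0, S=0)
    new, _ = step(s, params)
    assert new.H_alg == pytest.approx(0.05, rel=1e-12)


# ------------------------------------------------------------- step/simulate
def test_step_from_all_zero_state(params):
    zero = FoodWebState(A=0, D=0, H_alg=0, H_det=0, G_alg=0, G_det=0,
                        T=0, S=0)
    new, ledger = step(zero, params)
    assert new.D == params.I
    assert all(getattr(new, n) == 0 for n in
               ("A", "H_alg", "H_det", "G_alg", "G_det", "T", "S"))
    assert ledger["emergence_flux"] == 0.0


def test_donor_control_subsidy_conservation(params, ref_state):
    """Consumed + leftover terrestrial prey always equals the input X."""
    for T in (0.0, 1.0, 5.12, 10.24, 50.0):
        s = ref_state.replace(T=T)
        _, ledger = step(s, params)
        leftover = max(0.0, params.X - params.c_t * T)
        assert ledger["trout_terrestrial_intake"] + leftover == \
            pytest.approx(params.X, abs=1e-15)
        assert ledger["trout_terrestrial_intake"] <= params.X
        assert ledger["salamander_terrestrial_intake"] <= leftover + 1e-15


def test_one_step_matches_naive_oracle(params, ref_state):
    new, ledger = step(ref_state, params)
    oracle = naive_step(dict(zip(ref_state.__dataclass_fields__,
                                 ref_state.as_tuple())), params)
    for name in ("A", "D", "H_alg", "H_det", "G_alg", "G_det", "T", "S"):
        assert getattr(new, name) == pytest.approx(oracle[name], abs=1e-12)
    assert ledger["emergence_flux"] == pytest.approx(oracle["emergence"],
                                                     abs=1e-12)


@pytest.mark.parametrize("trout,sal", [(True, True), (True, False),
                                       (False, True), (False, False)])
def test_five_day_run_matches_naive_oracle(params, ref_state, trout, sal):
    traj = simulate(ref_state, params, days=5, trout_present=trout,
                    salamander_present=sal)
    pools = dict(zip(ref_state.__dataclass_fields__, ref_state.as_tuple()))
    for day in range(1, 6):
        pools = naive_step(pools, params, trout, sal)
        for name in ("A", "D", "H_alg", "H_det", "G_alg", "G_det", "T", "S"):
            assert traj.states.loc[day, name] == \
                pytest.approx(pools[name], abs=1e-10)


def test_algae_only_closed_form(params):
    """Without grazers algae compounds at b_a·(1−L) per day."""
    s = FoodWebState(A=1.59, D=0, H_alg=0, H_det=0, G_alg=0, G_det=0,
                     T=0, S=0)
    traj = simulate(s, params, days=90)
    r = 1 + params.b_a * (1 - params.L)
    for t in (1, 30, 90):
        assert traj.states.loc[t, "A"] == pytest.approx(1.59 * r ** t,
                                                        rel=1e-12)


def test_detritus_mass_balance_over_90_days(params, ref_state):
    traj = simulate(ref_state, params, days=90)
    consumed = traj.ledger["detritus_consumption"].cumsum()
    for t in (1, 45, 90):
        expected = ref_state.D + t * params.I - consumed.loc[t]
        assert traj.states.loc[t, "D"] == pytest.approx(expected, abs=1e-9)


def test_ledger_state_consistency(params, ref_state):
    """Ledger rows agree exactly with the state changes they describe."""
    traj = simulate(ref_state, params, days=90)
    for t in (1, 10, 60, 90):
        pre = traj.states.loc[t - 1]
        H_G = pre["H_alg"] + pre["H_det"] + pre["G_alg"] + pre["G_det"]
        assert traj.ledger.loc[t, "emergence_flux"] == \
            pytest.approx(params.e_h * H_G, abs=1e-12)
        # algae bookkeeping closes exactly
        assert traj.states.loc[t, "A"] == pytest.approx(
            pre["A"] + traj.ledger.loc[t, "algal_growth"]
            - traj.ledger.loc[t, "algal_grazing"], abs=1e-12)


def test_clamp_rescales_losses_proportionally(params):
    """Overdrawn prey pool lands at 0; predators grow on realized intake."""
    p = params.replace(alpha=0.01)  # predation saturates: demand >> pool
    s = FoodWebState(A=0.0, D=0.0, H_alg=0.004, H_det=0.004, G_alg=0,
                     G_det=0, T=50.0, S=0.0)
    new, ledger = step(s, p)
    assert new.H_alg == 0.0 and new.H_det == 0.0
    pred_demand = p.c_t * 50.0 * type3_fraction(0.008, p.alpha)
    scale = 0.008 / (pred_demand + (p.e_h + p.m_h) * 0.008)
    total_loss = (ledger["trout_aquatic_intake"] + ledger["emergence_flux"]
                  + p.m_h * 0.008 * scale)
    assert total_loss == pytest.approx(0.008, rel=1e-9)  # pool + zero growth
    # proportional rescaling preserves the loss composition
    demand_ratio = pred_demand / (p.e_h * 0.008)
    assert ledger["trout_aquatic_intake"] / ledger["emergence_flux"] == \
        pytest.approx(demand_ratio, rel=1e-9)
    assert new.T - s.T == pytest.approx(
        p.b_t * (ledger["trout_aquatic_intake"]
                 + ledger["trout_terrestrial_intake"]), abs=1e-11)


def test_monotone_trout_response_to_subsidy(params, ref_state):
    finals = [simulate(ref_state, params.replace(X=x), days=90).final["T"]
              for x in (0.0, 0.13, 0.261, 0.39, 0.522)]
    assert all(b >= a for a, b in zip(finals, finals[1:]))


def test_vulnerable_prey_non_increasing_in_initial_trout(params, ref_state):
    finals = [simulate(ref_state.replace(T=t), params, days=90).final["H"]
              for t in (0.0, 2.0, 5.12, 10.0, 20.0)]
    assert all(b <= a + 1e-12 for a, b in zip(finals, finals[1:]))


def test_saturation_limit_small_alpha(params):
    """As alpha → 0 the response saturates and intake → c·(predator)."""
    p = params.replace(alpha=1e-6)
    assert type3_fraction(0.05, p.alpha) == pytest.approx(1.0, abs=1e-6)
    s = FoodWebState(A=1, D=1, H_alg=5.0, H_det=5.0, G_alg=0, G_det=0,
                     T=5.12, S=0)
    _, ledger = step(s, p)
    assert ledger["trout_aquatic_intake"] == pytest.approx(0.075 * 5.12,
                                                           rel=1e-9)


def test_absent_predator_equals_zero_biomass(params, ref_state):
    flagged = simulate(ref_state, params, days=30, trout_present=False)
    zeroed = simulate(ref_state.replace(T=0.0), params, days=30)
    zeroed.states["T"] = flagged.states["T"]  # flagged keeps T frozen
    for col in ("A", "D", "H_alg", "H_det", "G_alg", "G_det", "S"):
        assert (flagged.states[col] == zeroed.states[col]).all()


def test_simulate_requires_at_least_one_day(params, ref_state):
    with pytest.raises(ValueError):
        simulate(ref_state, params, days=0)


def test_simulation_requires_calibrated_parameters(ref_state):
    with pytest.raises(UncalibratedParameterError):
        simulate(ref_state, ModelParams(), days=1)


# ---------------------------------------------------------- property tests
_pool = st.floats(min_value=0.0, max_value=50.0, allow_nan=False)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    A=_pool, D=_pool, Ha=_pool, Hd=_pool, Ga=_pool, Gd=_pool,
    T=_pool, S=_pool,
    alpha=st.floats(min_value=1e-3, max_value=10.0),
    m_h=st.floats(min_value=0.0, max_value=0.1),
    X=st.floats(min_value=0.0, max_value=1.0),
    trout=st.booleans(), sal=st.booleans(),
)
def test_pools_never_negative(A, D, Ha, Hd, Ga, Gd, T, S, alpha, m_h, X,
                              trout, sal):
    """Non-negativity holds for any admissible parameters and state."""
    p = ModelParams(alpha=alpha, m_h=m_h, X=X)
    s = FoodWebState(A=A, D=D, H_alg=Ha, H_det=Hd, G_alg=Ga, G_det=Gd,
                     T=T, S=S)
    traj = simulate(s, p, days=30, trout_present=trout,
                    salamander_present=sal)
    assert (traj.states >= 0).all().all()
    assert (traj.ledger >= 0).all().all()
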