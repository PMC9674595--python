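import numpy as np
import pytest
from scipy.stats import chisquare

from hncsim import (
    DomainError,
    ModelParams,
    StateError,
    monoclonal_probability,
    simulate,
    simulate_single_clone,
    transition_rate_tables,
    uniform_state,
    validate_state,
)
from hncsim._kernels import multiclone_focal_series


def test_uniform_state_largest_remainder():
    assert np.array_equal(uniform_state(ModelParams(K=10, N=100, epsilon=0.1)),
                          np.full(10, 10))
    st = uniform_state(ModelParams(K=3, N=10, epsilon=0.1))
    assert st.sum() == 10 and np.array_equal(np.sort(st)[::-1], [4, 3, 3])


def test_state_validation():
    p = ModelParams(K=3, N=10, epsilon=0.1)
    with pytest.raises(StateError):
        validate_state(p, np.array([5, 5, 1]))  # sums to 11
    with pytest.raises(StateError):
        validate_state(p, np.array([11, -1, 0]))
    with pytest.raises(StateError):
        validate_state(p, np.array([5, 5]))


def test_zero_steps_returns_initial_state(hnc_params):
    traj = simulate(hnc_params, n_steps=0, seed=1)
    assert traj.states.shape == (1, 10)
    assert np.array_equal(traj.states[0], uniform_state(hnc_params))
    assert traj.times[0] == 0.0


def test_conservation_on_every_snapshot(hnc_params):
    traj = simulate(hnc_params, n_steps=20_000, seed=3, record_every=97)
    assert np.all(traj.states.sum(axis=1) == hnc_params.N)
    assert np.all(traj.states >= 0)
    assert traj.record_steps[0] == 0 and traj.record_steps[-1] == 20_000
    assert np.all(np.diff(traj.times) > 0)


def test_identical_seed_identical_trajectory(hnc_params):
    a = simulate(hnc_params, n_steps=5000, seed=11, record_every=10)
    b = simulate(hnc_params, n_steps=5000, seed=11, record_every=10)
    c = simulate(hnc_params, n_steps=5000, seed=12, record_every=10)
    assert np.array_equal(a.states, b.states)
    assert not np.array_equal(a.states, c.states)


def test_trajectory_exports(hnc_params):
    traj = simulate(hnc_params, n_steps=100, seed=0, record_every=50)
    tidy = traj.to_tidy()
    assert set(tidy.columns) == {"step", "time", "clone", "size"}
    assert len(tidy) == 3 * hnc_params.K
    wide = traj.to_wide()
    assert wide.shape == (hnc_params.K, 3)
    assert np.allclose(wide.sum(axis=0), hnc_params.N)


def test_marginal_clone_matches_birth_death_kernel(hnc_params):
    """Bridge between the multi-clone simulator and the analytics.

    Transition counts of one clone inside the full simulation are
    compared, state by state, against the single-clone birth-death
    probabilities r_up/r_down via a chi-square goodness-of-fit test.
    """
    n_steps = 400_000
    series = multiclone_focal_series(
        uniform_state(hnc_params), hnc_params.epsilon, hnc_params.lam,
        n_steps, 202,
    )
    r_up, r_down = transition_rate_tables(hnc_params)
    pvals = []
    for n in range(101):
        at = np.flatnonzero(series[:-1] == n)
        if at.size < 500:
            continue
        nxt = series[at + 1]
        obs = np.array([(nxt == n + 1).sum(), (nxt == n - 1).sum(),
                        (nxt == n).sum()])
        exp = np.array([r_up[n], r_down[n], 1 - r_up[n] - r_down[n]]) * at.size
        keep = exp > 0
        stat, pv = chisquare(obs[keep], exp[keep])
        pvals.append(pv)
    assert len(pvals) >= 10
    # joint check: with ~30 independent tests, the minimum p-value should
    # not be absurdly small
    assert min(pvals) > 1e-5 / len(pvals)


def test_neutral_fixation_probability_is_initial_frequency(nc_params):
    """Classic neutral result: P(fix) = n0/N, via Monte Carlo."""
    n0, n_reps = 20, 10_000
    r_up, r_down = transition_rate_tables(nc_params)
    fixed = 0
    from hncsim._kernels import birth_death_checkpoints

    for r in range(n_reps):
        # run until absorption: neutral chains absorb well within 1e5 steps
        out = birth_death_checkpoints(
            n0, r_up, r_down, np.array([200_000]), 1000 + r
        )
        assert out[0] in (0, nc_params.N)
        fixed += out[0] == nc_params.N
    phat = fixed / n_reps
    se = np.sqrt(0.2 * 0.8 / n_reps)
    assert abs(phat - n0 / nc_params.N) < 3 * se


def test_supply_only_histogram_is_binomial(hier_params):
    """Telescoping the detailed-balance product at lam=0 gives
    Binomial(N, 1/K); the simulated occupation histogram agrees."""
    from scipy.stats import binom

    series = simulate_single_clone(hier_params, n0=10, n_steps=2_000_000, seed=8)
    hist = np.bincount(series[100_000:], minlength=101) / (series.size - 100_000)
    ref = binom.pmf(np.arange(101), 100, 0.1)
    assert 0.5 * np.abs(hist - ref).sum() < 0.02


def test_monoclonal_probability_interface(hnc_params):
    with pytest.raises(DomainError):
        monoclonal_probability(hnc_params, checkpoints=[], n_reps=10)
    with pytest.raises(DomainError):
        monoclonal_probability(hnc_params, checkpoints=[100], n_reps=0)
    out = monoclonal_probability(hnc_params, checkpoints=[10, 100], n_reps=5, seed=0)
    assert out.shape == (2,) and np.all((out >= 0) & (out <= 1))


def test_monoclonal_conversion_increases_over_time_in_nc(nc_params):
    frac = monoclonal_probability(
        nc_params, checkpoints=[2_000, 20_000, 200_000], n_reps=300, seed=7
    )
    assert frac[0] <= frac[1] <= frac[2]
    assert frac[2] == 1.0  # neutral drift always fixes eventually


def test_smaller_supply_gives_larger_monoclonal_plateau():
    lo = ModelParams(K=10, N=100, epsilon=0.01, lam=1.0)
    hi = ModelParams(K=10, N=100, epsilon=0.1, lam=1.0)
    f_lo = monoclonal_probability(lo, checkpoints=[300_000], n_reps=300, seed=5)
    f_hi = monoclonal_probability(hi, checkpoints=[300_000], n_reps=300, seed=5)
    assert f_lo[0] > f_hi[0] + 0.2
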