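"""Neural-mass model: sigmoid, connectivity, state equations, integrator."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import solve_ivp

from dcmerp import neural as nm


# ---------------------------------------------------------------------------
# firing-rate nonlinearity


def test_sigmoid_is_centered_at_rest():
    assert nm.sigmoid(0.0) == pytest.approx(0.0, abs=1e-15)


def test_sigmoid_matches_closed_form():
    # S(v) = 1/(1+exp(-r(v-eta))) - 1/(1+exp(r eta)) at r=0.56, eta=6
    r, eta = 0.56, 6.0
    for v in [-20.0, -3.0, 0.0, 2.5, 6.0, 14.0]:
        expected = 1.0 / (1.0 + np.exp(-r * (v - eta))) - 1.0 / (1.0 + np.exp(r * eta))
        assert nm.sigmoid(v) == pytest.approx(expected, abs=1e-12)
    # asymmetry of the centered form (not an odd function)
    assert nm.sigmoid(3.0) + nm.sigmoid(-3.0) != pytest.approx(0.0, abs=1e-6)


@given(st.floats(-30, 30), st.floats(-30, 30))
def test_sigmoid_strictly_increasing(v1, v2):
    if abs(v1 - v2) < 1e-9:
        return
    lo, hi = min(v1, v2), max(v1, v2)
    assert nm.sigmoid(lo) < nm.sigmoid(hi)


def test_sigmoid_bounded_and_overflow_safe():
    v = np.array([-1e6, -50.0, 0.0, 50.0, 1e6])
    s = nm.sigmoid(v)
    assert np.all(np.isfinite(s))
    assert np.all(np.abs(s) <= 1.0)


# ---------------------------------------------------------------------------
# model spec and parameter vector


def test_spec_rejects_nonzero_diagonal():
    F = np.eye(2, dtype=bool)
    Z = np.zeros((2, 2), dtype=bool)
    with pytest.raises(ValueError, match="diagonal"):
        nm.ModelSpec(2, F, Z, Z, np.array([True, False]))


def test_spec_rejects_modulation_outside_union(two_source):
    M = np.zeros((2, 2), dtype=bool)
    M[1, 1] = True
    with pytest.raises(ValueError, match="M_mask"):
        nm.ModelSpec(2, two_source.F_mask, two_source.B_mask,
                     two_source.L_mask, two_source.U_mask, M_mask=M)


def test_parameter_vector_length_equals_enabled_entries():
    spec = nm.two_source_spec(backward=True, lateral=True,
                              conditions=["std", "dev"], modulate_all=True)
    n_extrinsic = int(spec.F_mask.sum() + spec.B_mask.sum() + spec.L_mask.sum())
    n_mod = int(spec.M_mask.sum()) * (len(spec.conditions) - 1)
    assert spec.n_free == n_extrinsic + int(spec.U_mask.sum()) + n_mod


@given(st.integers(0, 2**31 - 1))
def test_parameter_vector_roundtrip_lossless(seed):
    spec = nm.two_source_spec(backward=True, lateral=True,
                              conditions=["std", "dev"], modulate_all=True)
    rng = np.random.default_rng(seed)
    pv = nm.ParameterVector(spec, rng.standard_normal(spec.n_free))
    back = nm.ParameterVector.from_structured(spec, pv.to_structured())
    np.testing.assert_array_equal(back.values, pv.values)


def test_spec_json_roundtrip(two_source):
    back = nm.ModelSpec.from_json(two_source.to_json())
    np.testing.assert_array_equal(back.F_mask, two_source.F_mask)
    np.testing.assert_array_equal(back.U_mask, two_source.U_mask)
    assert back.conditions == two_source.conditions
    assert back.base == two_source.base
    assert back.n_free == two_source.n_free


# ---------------------------------------------------------------------------
# effective connectivity


def test_connectivity_prior_means_at_zero_theta(two_source, theta0):
    F, B, L, U = nm.effective_connectivity(two_source, theta0, "standard")
    assert F[1, 0] == two_source.connection_means["F"]
    assert B[0, 1] == two_source.connection_means["B"]
    assert U[0] == two_source.connection_means["U"]
    assert F[0, 1] == 0.0 and L.sum() == 0.0 and U[1] == 0.0


def test_connectivity_modulation_doubles_entry():
    spec = nm.two_source_spec(conditions=["std", "dev"], modulate_all=True)
    pv = nm.ParameterVector(spec)
    pv[("mod", "dev", 1, 0)] = np.log(2.0)
    F_std, _, _, _ = nm.effective_connectivity(spec, pv, "std")
    F_dev, _, _, _ = nm.effective_connectivity(spec, pv, "dev")
    assert F_dev[1, 0] == pytest.approx(2.0 * F_std[1, 0], rel=1e-12)


def test_connectivity_masked_entries_zero_for_any_theta(two_source):
    rng = np.random.default_rng(3)
    pv = nm.ParameterVector(two_source, rng.standard_normal(3) * 2)
    F, B, L, U = nm.effective_connectivity(two_source, pv, "standard")
    assert F[0, 1] == 0.0 and B[1, 0] == 0.0 and np.all(L == 0.0)


def test_connectivity_unknown_condition_errors(two_source, theta0):
    with pytest.raises(ValueError, match="unknown condition"):
        nm.effective_connectivity(two_source, theta0, "oddball")


# ---------------------------------------------------------------------------
# state equations


def test_rest_is_a_fixed_point(two_source, theta0):
    f = nm.state_derivative(np.zeros(18), 0.0, two_source, theta0)
    np.testing.assert_array_equal(f, np.zeros(18))


def test_state_dimension_mismatch_errors(two_source, theta0):
    with pytest.raises(ValueError, match="state"):
        nm.state_derivative(np.zeros(17), 0.0, two_source, theta0)


def test_synaptic_drive_linear_in_gain():
    Z = np.zeros((1, 1), dtype=bool)
    U = np.array([True])
    s1 = nm.ModelSpec(1, Z, Z, Z, U, base=nm.SourceParameters(H_e=4.0))
    s2 = nm.ModelSpec(1, Z, Z, Z, U, base=nm.SourceParameters(H_e=8.0))
    f1 = nm.state_derivative(np.zeros(9), 1.0, s1, nm.ParameterVector(s1))
    f2 = nm.state_derivative(np.zeros(9), 1.0, s2, nm.ParameterVector(s2))
    np.testing.assert_allclose(f2, 2.0 * f1, rtol=1e-12)


@pytest.mark.parametrize("n_random", [10])
def test_system_jacobian_matches_finite_differences(two_source, theta0, n_random):
    rng = np.random.default_rng(2024)
    states = [np.zeros(18)] + [rng.standard_normal(18) * 3 for _ in range(n_random)]
    eps = 1e-6
    for x in states:
        J = nm.system_jacobian(x, 0.4, two_source, theta0)
        Jfd = np.empty_like(J)
        for i in range(18):
            e = np.zeros(18)
            e[i] = eps
            Jfd[:, i] = (nm.state_derivative(x + e, 0.4, two_source, theta0)
                         - nm.state_derivative(x - e, 0.4, two_source, theta0)) / (2 * eps)
        assert np.abs(J - Jfd).max() < 1e-6


def test_jacobian_block_diagonal_without_extrinsic_connections():
    Z = np.zeros((2, 2), dtype=bool)
    spec = nm.ModelSpec(2, Z, Z, Z, np.array([True, True]))
    J = nm.system_jacobian(np.ones(18), 0.5, spec, nm.ParameterVector(spec))
    assert np.abs(J[:9, 9:]).max() == 0.0
    assert np.abs(J[9:, :9]).max() == 0.0


def test_rest_point_is_stable(two_source, theta0):
    """All dynamical modes decay; the only zero modes are the structural
    redundancy of the pyramidal depolarization state (one per source)."""
    J = nm.system_jacobian(np.zeros(18), 0.0, two_source, theta0)
    ev = np.sort(np.linalg.eigvals(J).real)
    assert np.all(ev <= 1e-12)
    assert np.sum(np.abs(ev) < 1e-12) == two_source.n_sources
    assert ev[-(two_source.n_sources + 1)] < -1e-3


# ---------------------------------------------------------------------------
# integration


def test_zero_input_zero_trajectory(two_source, theta0, short_grid):
    silent = nm.StimulusInput(amplitude=0.0)
    traj = nm.integrate(two_source, theta0, "standard", silent, short_grid)
    assert np.abs(traj).max() == 0.0


def test_integrator_matches_high_accuracy_ode_oracle(two_source, theta0, stim):
    grid = np.arange(0.0, 501.0, 1.0)
    traj = nm.integrate(two_source, theta0, "standard", stim, grid)
    comp = nm._Compiled(two_source, theta0, "standard")

    def rhs(t, x):
        return comp.derivative(x, stim.sample(np.array([t]))[0])

    sol = solve_ivp(rhs, (0.0, 500.0), np.zeros(18), t_eval=grid,
                    rtol=1e-10, atol=1e-13, method="DOP853")
    ref = sol.y.reshape(2, 9, -1)[:, 8, :]
    peak = np.abs(ref).max()
    assert np.abs(traj - ref).max() <= 1e-3 * peak


def test_time_invariance_under_input_shift(two_source, theta0):
    # onsets deep inside the window so the truncated Gaussian tails at the
    # grid edge are negligible on both runs
    grid = np.arange(0.0, 500.0, 1.0)
    early = nm.integrate(two_source, theta0, "standard",
                         nm.StimulusInput(onset=120.0), grid)
    late = nm.integrate(two_source, theta0, "standard",
                        nm.StimulusInput(onset=170.0), grid)
    peak = np.abs(early).max()
    np.testing.assert_allclose(late[:, 50:], early[:, :-50], atol=1e-6 * peak)


def test_single_synapse_impulse_response_kernel():
    """With intrinsic coupling off, the stellate response to a one-sample
    pulse is the second-order synaptic kernel ~ H_e (t/tau_e) exp(-t/tau_e)."""
    Z = np.zeros((1, 1), dtype=bool)
    spec = nm.ModelSpec(1, Z, Z, Z, np.array([True]),
                        base=nm.SourceParameters(gamma=(0, 0, 0, 0)))
    pv = nm.ParameterVector(spec)
    dt = 0.05
    grid = np.arange(0.0, 80.0 + dt / 2, dt)
    amp = 1e-3  # small-signal regime
    stim = nm.StimulusInput(onset=0.0, width=0.0, amplitude=amp)
    # pyramidal output is silent (gamma2 = 0); recover stellate voltage from
    # a one-source integration by re-running with gamma2 > 0 disabled and
    # reading the analytic form instead
    comp = nm._Compiled(spec, pv, "standard")
    # area of the one-step pulse is amp*dt
    base = spec.base
    ke = base.H_e / base.tau_e / 1000.0
    t = grid
    expected = amp * dt * ke * comp.CU[0] * t * np.exp(-t / base.tau_e)
    # integrate the 9-state system and read the stellate state via the
    # derivative identity: track it with a fine manual LL run
    x = np.zeros(9)
    stell = np.empty(grid.size)
    stell[0] = 0.0
    from scipy.linalg import expm

    u = stim.sample(grid)
    red = [c for c in range(9) if c != 8]
    for k in range(grid.size - 1):
        J = comp.jacobian(x, u[k])[np.ix_(red, red)]
        f = comp.derivative(x, u[k])[red]
        M = np.zeros((9, 9))
        M[:8, :8] = J
        M[:8, 8] = f
        dx = expm(dt * M)[:8, 8]
        x[red] += dx
        stell[k + 1] = x[0]
    mask = t > 2.0  # skip the pulse step itself
    peak = np.abs(expected).max()
    assert np.abs(stell[mask] - expected[mask]).max() < 0.02 * peak


def test_divergence_raises_with_time_index(two_source, theta0, stim):
    # an astronomically large initial state overflows the first update
    grid = np.arange(0.0, 20.0, 1.0)
    with pytest.raises(nm.IntegrationDivergedError) as err:
        with np.errstate(all="ignore"):
            nm.integrate(two_source, theta0, "standard", stim, grid,
                         x0=np.full(18, 1e308))
    assert err.value.time_index >= 1


def test_non_monotone_grid_rejected(two_source, theta0, stim):
    with pytest.raises(ValueError, match="increasing"):
        nm.integrate(two_source, theta0, "standard", stim,
                     np.array([0.0, 2.0, 1.0]))


def test_output_insensitive_to_modulation_in_baseline():
    spec = nm.two_source_spec(conditions=["std", "dev"], modulate_all=True)
    grid = np.arange(0.0, 200.0, 2.0)
    stim = nm.StimulusInput()
    pv = nm.ParameterVector(spec)
    t1 = nm.integrate(spec, pv, "std", stim, grid)
    pv2 = pv.copy()
    for entry in pv2.index:
        if entry[0] == "mod":
            pv2[entry] = 0.7
    t2 = nm.integrate(spec, pv2, "std", stim, grid)
    np.testing.assert_array_equal(t1, t2)
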