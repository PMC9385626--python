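import numpy as np
import pytest

import hypernf as H


@pytest.fixture(scope="session")
def ring4():
    return H.fixture("ring4")


@pytest.fixture(scope="session")
def path3():
    return H.fixture("path3")


@pytest.fixture(scope="session")
def kuramoto4_small():
    return H.fixture("kuramoto4", N=2000)


@pytest.fixture(scope="session")
def ring4_nf(ring4):
    return H.normal_form(ring4)


@pytest.fixture(scope="session")
def ring4_hypernet(ring4_nf):
    return H.build_hypernetwork(ring4_nf)


#: ring-of-4 with the experimentally-motivated 1% pairwise detuning between
#: oscillators 2 and 4, used by the recovery studies (the exact printed values
#: make sin/cos of the two triplet phases collinear regressors)
RECOVERY_OMEGAS = (1.0, 2.53, 1.56, 2.54)


def simulate_and_fit(alpha, seed, T=2500, omegas=RECOVERY_OMEGAS, passes=4):
    """Shared recovery pipeline: simulate ring4, smooth, LASSO-fit triplets."""
    from hypernf.recover import default_window, PhaseSeries

    net = H.fixture("ring4", alpha=alpha, omegas=omegas)
    traj = H.simulate_network(net, T=T, dt=0.01, seed=seed, save_dt=0.1)
    ps = H.extract_phases(traj)
    window = default_window(float(np.mean(np.abs(net.omegas))))
    ps = H.smooth_frequency(ps, window=window, order=1, passes=passes)
    edge = int(2 * window / ps.dt)
    ps = PhaseSeries(ps.times[edge:-edge], ps.theta[edge:-edge], ps.dtheta[edge:-edge], {})
    tol = 0.05 * float(np.mean(np.abs(net.omegas)))
    combos = H.detect_resonances(net.omegas, tol, 2, 3)
    fit = H.fit_triplet_model(ps, combos)
    return net, combos, fit


def ring_support_ok(combos, fit):
    """Check the recovered support against the theoretical hyperedge pattern:
    nodes 1, 3 carry both triplet phases, node 2 only θ1−θ2+θ3, node 4 only
    θ1+θ3−θ4, and the pairwise θ2−θ4 candidate is rejected everywhere."""
    lab = [c.label() for c in combos]
    i1, i2 = lab.index("th1-th2+th3"), lab.index("th1+th3-th4")
    got = fit.support_pattern()
    return (
        set(got[0]) == {i1, i2}
        and set(got[1]) == {i1}
        and set(got[2]) == {i1, i2}
        and set(got[3]) == {i2}
    )
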