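import numpy as np
import pytest

from comanet import (
    CohortSpec,
    ParameterError,
    apply_injury,
    generate_cohort,
    generate_control_network,
    generate_probability_volumes,
    rewire_degree_preserving,
)
from comanet.metrics import clustering_coefficient_bd, degree_directed
from comanet.threshold import binarize, threshold_absolute
from scipy.stats import kendalltau


def ring_spec(**kw):
    base = dict(n_nodes=10, k_ring=2, beta_rewire=0.0, hub_boost=0.0,
                groups=(("Control", 1, 1, 0.0),))
    base.update(kw)
    return CohortSpec(**base)


def test_pure_ring_lattice_degrees():
    net = generate_control_network(ring_spec(), seed=3)
    a = net.weights > 0
    assert (a.sum(axis=0) == 4).all() and (a.sum(axis=1) == 4).all()


def test_generator_is_deterministic():
    spec = CohortSpec(n_nodes=30, k_ring=3, seed=11,
                      groups=(("Control", 2, 2, 0.0), ("No AR", 2, 1, 0.5)))
    a = generate_control_network(spec, seed=5).weights
    b = generate_control_network(spec, seed=5).weights
    assert np.array_equal(a, b)
    ca, cb = generate_cohort(spec), generate_cohort(spec)
    assert len(ca) == len(cb)
    for ra, rb in zip(ca, cb):
        assert (ra.participant_id, ra.scan_index) == (rb.participant_id, rb.scan_index)
        assert np.array_equal(ra.network.weights, rb.network.weights)


def test_generated_weights_valid_across_seeds():
    spec = CohortSpec(n_nodes=40, k_ring=4, seed=0, groups=(("Control", 1, 1, 0.0),))
    for seed in range(10):
        w = generate_control_network(spec, seed).weights
        assert (w >= 0).all() and (w <= 1).all()
        assert np.diagonal(w).sum() == 0


def test_small_world_base_beats_rewired_null():
    # without rewiring/hubs the ring lattice is maximally clustered among
    # degree-matched graphs: rewired nulls must lose triangles on average
    spec = ring_spec(n_nodes=30, k_ring=3)
    real, null = [], []
    for seed in range(20):
        net = binarize(generate_control_network(spec, seed))
        real.append(clustering_coefficient_bd(net).mean())
        rnd = rewire_degree_preserving(net, iter_per_edge=20, seed=seed + 100)
        null.append(clustering_coefficient_bd(rnd).mean())
    assert np.mean(real) > np.mean(null)


def test_injury_identity_and_full_attenuation():
    net = generate_control_network(ring_spec(), seed=1)
    same = apply_injury(net, s=0.0, gamma=0.0, hub_nodes=(), sigma=0.0, seed=0)
    assert np.array_equal(same.weights, net.weights)
    dead = apply_injury(net, s=1.0, gamma=0.0, hub_nodes=(), sigma=0.0, seed=0)
    assert not dead.weights.any()


def test_injury_hub_selective_attenuation_factors():
    # a_ij = s(1 + gamma*H)/(1 + gamma): gamma=4, s=0.5 -> 0.5 on hub edges,
    # 0.1 on the rest
    net = generate_control_network(ring_spec(n_nodes=12, hub_boost=0.0), seed=2)
    hubs = (0, 1)
    out = apply_injury(net, s=0.5, gamma=4.0, hub_nodes=hubs, sigma=0.0, seed=0)
    w, wp = net.weights, out.weights
    mask = w > 0
    hub = np.zeros(12, dtype=bool)
    hub[list(hubs)] = True
    touches = hub[:, None] | hub[None, :]
    ratio = np.zeros_like(w)
    ratio[mask] = 1.0 - wp[mask] / w[mask]
    assert np.allclose(ratio[mask & touches], 0.5)
    assert np.allclose(ratio[mask & ~touches], 0.1)


def test_injury_monotone_in_severity_and_hub_selective():
    net = generate_control_network(CohortSpec(seed=4), seed=4)
    hubs = (66, 67, 72, 73, 76, 77)
    prev = net.weights
    for s in (0.1, 0.3, 0.5, 0.8):
        cur = apply_injury(net, s, gamma=2.0, hub_nodes=hubs, sigma=0.0, seed=0).weights
        assert (cur <= prev + 1e-15).all()
        prev = cur
    # relative loss on hub-incident edges strictly exceeds non-hub loss
    injured = apply_injury(net, 0.4, gamma=2.0, hub_nodes=hubs, sigma=0.0, seed=0)
    w, wp = net.weights, injured.weights
    hub = np.zeros(w.shape[0], dtype=bool)
    hub[list(hubs)] = True
    touches = hub[:, None] | hub[None, :]
    mask = w > 0
    loss = 1.0 - wp[mask] / w[mask]
    assert loss[touches[mask]].mean() > loss[~touches[mask]].mean()


def test_injury_rejects_negative_parameters():
    net = generate_control_network(ring_spec(), seed=1)
    with pytest.raises(ParameterError):
        apply_injury(net, s=-0.1, gamma=0.0, hub_nodes=(), sigma=0.0, seed=0)
    with pytest.raises(ParameterError):
        apply_injury(net, s=0.1, gamma=0.0, hub_nodes=(), sigma=-1.0, seed=0)


def test_cohort_counts():
    default = CohortSpec(seed=0)
    records = generate_cohort(default)
    controls = [r for r in records if r.group == "Control"]
    assert len(controls) == 12  # 4 participants x 3 repeat scans
    assert len({(r.participant_id, r.scan_index) for r in records}) == len(records)

    tiny = CohortSpec(n_nodes=10, k_ring=2, seed=0,
                      groups=(("A", 2, 1, 0.0), ("B", 3, 1, 0.5)))
    assert len(generate_cohort(tiny)) == 5


def test_cohort_rejects_empty_groups():
    with pytest.raises(ParameterError):
        CohortSpec(groups=())
    with pytest.raises(ParameterError):
        CohortSpec(groups=(("A", 0, 1, 0.0),))


def test_recovery_group_degree_decreases_with_severity():
    # thresholded global degree must fall monotonically across the
    # severity-ordered groups of a default-style cohort
    spec = CohortSpec(
        seed=21,
        groups=(
            ("Control", 6, 3, 0.0),
            ("EMCS", 6, 1, 0.15),
            ("AR'", 6, 1, 0.35),
            ("No AR", 6, 1, 0.55),
        ),
    )
    severities, means = [], []
    records = generate_cohort(spec)
    for sev, group in [(0.0, "Control"), (0.15, "EMCS"), (0.35, "AR'"), (0.55, "No AR")]:
        nets = [r.network for r in records if r.group == group]
        k = [
            degree_directed(binarize(threshold_absolute(n, 0.10))).degree.mean()
            for n in nets
        ]
        severities.append(sev)
        means.append(np.mean(k))
    assert all(a > b for a, b in zip(means, means[1:]))
    tau, p = kendalltau(severities, means)
    assert tau < 0


def test_probability_volumes_partition_and_oracle_means():
    labels, maps, means = generate_probability_volumes((6, 6, 6), 2, ("constant", 0.4), 3)
    assert sorted(np.unique(labels)) == [1, 2]
    assert len(maps) == 2
    assert np.allclose(means, 0.4)
    # disjoint blocks: every voxel carries exactly one label
    assert labels.size == (labels == 1).sum() + (labels == 2).sum()

    l2, m2, mu2 = generate_probability_volumes((6, 6, 6), 2, ("constant", 0.4), 3)
    assert np.array_equal(labels, l2)
    assert all(np.array_equal(a, b) for a, b in zip(maps, m2))

    with pytest.raises(ParameterError):
        generate_probability_volumes((2, 6, 6), 5, ("constant", 0.4), 0)
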