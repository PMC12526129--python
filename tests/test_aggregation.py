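"""Aggregation-analysis tests: clustering, kinetics, registry, fractions."""

import numpy as np
import pytest

from hybridff.aggregation import (
    FrameRegistry,
    RegistryAssignment,
    amyloid_fractions,
    classify_registry,
    com_distance_series,
    detect_beta_strands,
    encounter_events,
    find_clusters,
    fit_growth_exponent,
)
from hybridff.fixtures import (
    build_alpha_helix,
    build_beta_sheet,
    strand_segments_from_sheet,
    synth_growth_series,
    synth_oscillating_distance_series,
)
from hybridff.system import ParticleSystem


def chains_system(chain_positions, box=None):
    """System with one 1-particle chain per given position (or several)."""
    pos, chains = [], []
    for c, p in enumerate(chain_positions):
        p = np.atleast_2d(p)
        pos.extend(p)
        chains.extend([c] * len(p))
    return ParticleSystem.create(
        np.asarray(pos, dtype=float), chains=np.asarray(chains), masses=72.0, box=box
    )


def union_find_oracle(system, cutoff):
    """Brute-force union-find over all chain pairs (independent oracle)."""
    chains = sorted(set(system.chains.tolist()))
    parent = {c: c for c in chains}

    def find(c):
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    for a in chains:
        for b in chains:
            if a >= b:
                continue
            pa = system.positions[system.chains == a]
            pb = system.positions[system.chains == b]
            linked = False
            for x in pa:
                for y in pb:
                    d = x - y
                    if system.box is not None:
                        d = d - system.box * np.round(d / system.box)
                    if np.linalg.norm(d) < cutoff:
                        linked = True
                        break
                if linked:
                    break
            if linked:
                parent[find(a)] = find(b)
    groups = {}
    for c in chains:
        groups.setdefault(find(c), set()).add(c)
    return {frozenset(g) for g in groups.values()}


class TestClustering:
    def test_all_far_apart_gives_singletons(self):
        system = chains_system([[0, 0, 0], [2, 0, 0], [0, 2, 0]])
        cs = find_clusters(system, cutoff=0.6)
        assert sorted(len(c) for c in cs.clusters) == [1, 1, 1]

    def test_single_linkage_transitivity(self):
        system = chains_system([[0, 0, 0], [0.5, 0, 0], [1.0, 0, 0]])
        cs = find_clusters(system, cutoff=0.6)
        assert cs.clusters == [frozenset({0, 1, 2})]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_union_find_oracle_on_50_chains(self, seed):
        rng = np.random.default_rng(seed)
        chain_positions = [rng.uniform(0, 5, size=(3, 3)) for _ in range(50)]
        system = chains_system(chain_positions, box=np.array([5.0, 5.0, 5.0]))
        cs = find_clusters(system, cutoff=0.6)
        assert set(cs.clusters) == union_find_oracle(system, 0.6)

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(3)
        system = chains_system([rng.uniform(0, 3, size=(2, 3)) for _ in range(20)])
        small = find_clusters(system, cutoff=0.4)
        large = find_clusters(system, cutoff=0.9)
        # every small-cutoff cluster is contained in one large-cutoff cluster
        for cl in small.clusters:
            assert any(cl <= big for big in large.clusters)

    def test_chain_relabeling_invariance(self):
        rng = np.random.default_rng(4)
        positions = [rng.uniform(0, 3, size=(2, 3)) for _ in range(10)]
        system = chains_system(positions)
        cs = find_clusters(system, cutoff=0.6)
        relabel = {c: 9 - c for c in range(10)}
        system2 = chains_system(positions)
        system2.chains[:] = [relabel[c] for c in system2.chains]
        cs2 = find_clusters(system2, cutoff=0.6)
        assert {frozenset(relabel[c] for c in cl) for cl in cs.clusters} == set(cs2.clusters)

    def test_empty_selection_rejected(self):
        system = chains_system([[0, 0, 0]])
        with pytest.raises(ValueError):
            find_clusters(system, chain_selection=[], cutoff=0.6)


class TestGrowthExponent:
    def test_noiseless_power_law_exact(self):
        series = synth_growth_series(alpha=0.91, noise_sd=0.0, seed=0)
        fit = fit_growth_exponent(series)
        assert fit.alpha == pytest.approx(0.91, abs=1e-10)

    def test_constant_series_zero_exponent(self):
        series = synth_growth_series(alpha=0.0, noise_sd=0.0, seed=0)
        assert fit_growth_exponent(series).alpha == pytest.approx(0.0, abs=1e-12)

    def test_noisy_quarter_exponent_recovery_over_seeds(self):
        """Reaction-limited alpha = 0.25 recovered within 2 SE per seed."""
        hits = 0
        for seed in range(20):
            series = synth_growth_series(alpha=0.25, n_points=50, noise_sd=0.1, seed=seed)
            fit = fit_growth_exponent(series)
            if abs(fit.alpha - 0.25) <= 2 * fit.stderr:
                hits += 1
        assert hits >= 18  # ~95% coverage of a 2-SE interval

    def test_equals_closed_form_ols_slope(self):
        series = synth_growth_series(alpha=0.5, noise_sd=0.2, seed=5)
        x, y = np.log(series.times), np.log(series.sizes)
        slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        assert fit_growth_exponent(series).alpha == pytest.approx(slope, rel=1e-12)

    def test_fit_range_restricts_points(self):
        series = synth_growth_series(alpha=0.91, noise_sd=0.0, seed=0, t_span=(1.0, 100.0))
        fit = fit_growth_exponent(series, fit_range=(5.0, 50.0))
        assert fit.n_points < len(series.times)
        assert fit.alpha == pytest.approx(0.91, abs=1e-10)

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError):
            fit_growth_exponent((np.arange(-2, 8), np.ones(10)))


class TestComDistance:
    def test_identical_member_sets_give_zero(self):
        system = chains_system([[0, 0, 0], [0.3, 0, 0]])
        series = com_distance_series([system], {0, 1}, {0, 1}, track_fusion=False)
        assert series.distances == pytest.approx([0.0])

    def test_periodic_minimum_image_hand_values(self):
        box = np.array([3.0, 3.0, 3.0])
        # chains at x=0.2 and x=2.8: minimum image separation 0.4 nm = 4 A
        system = chains_system([[0.2, 1.0, 1.0], [2.8, 1.0, 1.0]], box=box)
        series = com_distance_series([system], {0}, {1}, track_fusion=False)
        assert series.distances == pytest.approx([4.0])

    def test_oscillating_series_counts_three_encounters_no_fusion(self):
        t, d = synth_oscillating_distance_series(n_dips=3)
        events = encounter_events(t, d, threshold=30.0)
        assert len(events) == 3

    def test_cluster_vanishing_is_tracking_error(self):
        a = chains_system([[0, 0, 0], [1, 0, 0]])
        with pytest.raises(ValueError, match="frame 0"):
            com_distance_series([a], {0}, {7}, track_fusion=False)

    def test_fusion_detected_when_sets_merge(self):
        near = chains_system([[0, 0, 0], [0.3, 0, 0]])
        far = chains_system([[0, 0, 0], [2.0, 0, 0]])
        series = com_distance_series([far, near], {0}, {1}, threshold=10.0, cluster_cutoff=0.6)
        assert series.fusions == [1.0]


class TestBetaStrandDetection:
    def test_ideal_sheet_detected_full_length(self):
        sheet = build_beta_sheet(2, "parallel")
        segments = detect_beta_strands(sheet)
        assert len(segments) == 2
        assert all(len(s.residues) == 5 for s in segments)

    def test_alpha_helix_yields_no_strands(self):
        helix = build_alpha_helix(8)
        assert detect_beta_strands(helix) == []

    def test_isolated_extended_chain_needs_a_partner(self):
        sheet = build_beta_sheet(2, "parallel")
        lone = ParticleSystem.create(
            sheet.positions[sheet.chains == 0],
            types="CA",
            masses=110.0,
            chains=0,
            resnames=np.asarray(["L1", "V2", "F3", "F4", "A5"], dtype=object),
        )
        assert detect_beta_strands(lone) == []

    def test_chain_without_backbone_warns_and_skips(self):
        sheet = build_beta_sheet(2, "parallel")
        sheet.types[sheet.chains == 1] = "SC"
        with pytest.warns(UserWarning, match="chain 1"):
            segments = detect_beta_strands(sheet)
        assert segments == []


class TestRegistryClassification:
    def classify_sheet(self, registry, shift=0):
        sheet = build_beta_sheet(2, registry, shift)
        a, b = strand_segments_from_sheet(sheet)
        return sheet, a, b, classify_registry(sheet, a, b)

    def test_parallel_in_register_is_parallel_amyloid(self):
        _, _, _, res = self.classify_sheet("parallel")
        assert res.label == "parallel-amyloid"
        assert res.orientation == "parallel" and res.in_register

    def test_antiparallel_in_register_template(self):
        _, _, _, res = self.classify_sheet("antiparallel")
        assert res.label == "antiparallel-amyloid"
        assert res.pairing == {"L1": "F4", "V2": "F3", "F3": "V2", "F4": "L1"}

    def test_one_residue_shift_is_off_register(self):
        _, _, _, res = self.classify_sheet("parallel", shift=1)
        assert res.label == "other"
        assert res.orientation == "parallel" and not res.in_register

    @pytest.mark.parametrize("registry", ["parallel", "antiparallel"])
    def test_classification_symmetric(self, registry):
        sheet, a, b, res = self.classify_sheet(registry)
        swapped = classify_registry(sheet, b, a)
        assert swapped.label == res.label
        assert swapped.orientation == res.orientation

    def test_short_strands_unclassifiable(self):
        sheet = build_beta_sheet(2, "parallel")
        a, b = strand_segments_from_sheet(sheet)
        from hybridff.aggregation import StrandSegment

        short = StrandSegment(a.chain, a.residues[:2], a.ca_indices[:2], a.labels[:2])
        assert classify_registry(sheet, short, b).label == "unclassifiable"

    def test_label_invariant_enforced(self):
        with pytest.raises(ValueError):
            RegistryAssignment((0, 1), "antiparallel", False, {}, "parallel-amyloid")


def make_assignment(label):
    orient = {"parallel-amyloid": "parallel", "antiparallel-amyloid": "antiparallel"}.get(label, "other")
    return RegistryAssignment((0, 1), orient, label.endswith("amyloid"), {}, label)


class TestAmyloidFractions:
    def test_all_parallel_fixture(self):
        frame = FrameRegistry(
            assignments=[make_assignment("parallel-amyloid")] * 5,
            strand_residues=40,
            cluster_residues=100,
        )
        f = amyloid_fractions([frame])
        assert (f.amyloid_fraction, f.parallel_fraction, f.antiparallel_fraction) == (1.0, 1.0, 0.0)
        assert f.beta_fraction == pytest.approx(0.4)

    def test_mixed_fixture_counts_exactly(self):
        """6 parallel + 4 antiparallel + 15 other pairs: 40%/24%/16%."""
        assignments = (
            [make_assignment("parallel-amyloid")] * 6
            + [make_assignment("antiparallel-amyloid")] * 4
            + [make_assignment("other")] * 15
        )
        frame = FrameRegistry(assignments=assignments, strand_residues=40, cluster_residues=100)
        f = amyloid_fractions([frame])
        assert f.amyloid_fraction == pytest.approx(0.40)
        assert f.parallel_fraction == pytest.approx(0.24)
        assert f.antiparallel_fraction == pytest.approx(0.16)

    def test_frame_order_invariance(self):
        frames = [
            FrameRegistry([make_assignment("parallel-amyloid")] * 3, 10, 30),
            FrameRegistry([make_assignment("other")] * 2, 5, 50),
            FrameRegistry([make_assignment("antiparallel-amyloid")], 8, 20),
        ]
        a = amyloid_fractions(frames)
        b = amyloid_fractions(frames[::-1])
        assert a == b

    def test_zero_strands_flagged(self):
        frame = FrameRegistry(assignments=[], strand_residues=0, cluster_residues=50)
        f = amyloid_fractions([frame])
        assert f.flagged_empty
        assert f.amyloid_fraction == 0.0

    def test_cluster_size_weighting(self):
        big = FrameRegistry([make_assignment("parallel-amyloid")], 90, 90)
        small = FrameRegistry([make_assignment("other")], 0, 10)
        f = amyloid_fractions([big, small])
        assert f.amyloid_fraction == pytest.approx(0.9)
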