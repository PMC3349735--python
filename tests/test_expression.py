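"""Probeset collapsing, differential response, z-profiles and clustering."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from tfbindmode import expression
from tfbindmode.expression import (
    CONDITIONS,
    collapse_probesets,
    cluster_mode_association,
    differential_response,
    direction_mode_split,
    filter_regulated,
    kmeans_cluster,
    z_transform_profiles,
)
from tfbindmode.synthgen import SimConfig, generate_bundle


def make_matrix(effects, noise_sd=0.0, n_reps=3, baseline=2.0, seed=0):
    """Probeset matrix for the 2x2 design from per-probeset condition deltas.

    ``effects`` maps probeset -> length-4 tuple of condition offsets in the
    canonical condition order (control 0', control 30', kd 0', kd 30').
    """
    rng = np.random.default_rng(seed)
    samples, design_rows = [], []
    for (t, s) in CONDITIONS:
        for b in range(1, n_reps + 1):
            sid = f"{t}_{s}min_b{b}"
            samples.append(sid)
            design_rows.append({"sample": sid, "treatment": t, "stimulus": s, "batch": b})
    design = pd.DataFrame(design_rows).set_index("sample")
    rows = {}
    for ps, deltas in effects.items():
        sig = []
        for ci, _ in enumerate(CONDITIONS):
            for _ in range(n_reps):
                sig.append(baseline + deltas[ci] + rng.normal(0, noise_sd))
        rows[ps] = sig
    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    return matrix, design


class TestCollapseProbesets:
    def test_largest_change_probeset_retained(self):
        matrix, design = make_matrix({
            "G_ps1": (0, 0, 2.0, 2.0),     # knockdown effect +2.0
            "G_ps2": (0, 0, 0.5, 0.5),     # knockdown effect +0.5
        }, noise_sd=0.01, seed=1)
        gm, log = collapse_probesets(matrix, {"G_ps1": "G", "G_ps2": "G"}, design,
                                     background_level=0.0)
        assert list(gm.index) == ["G"]
        assert gm.loc["G"].equals(matrix.loc["G_ps1"])
        assert set(log.loc[log["rule"] == "not_largest_change", "probeset"]) == {"G_ps2"}

    def test_opposite_direction_gene_excluded(self):
        matrix, design = make_matrix({
            "H_ps1": (0, 0, 2.0, 2.0),
            "H_ps2": (0, 0, -1.0, -1.0),
        }, noise_sd=0.01, seed=2)
        gm, log = collapse_probesets(matrix, {"H_ps1": "H", "H_ps2": "H"}, design,
                                     background_level=0.0)
        assert "H" not in gm.index
        assert (log["rule"] == "opposite_directions").sum() == 2

    def test_below_background_dropped_before_other_rules(self):
        matrix, design = make_matrix({
            "L_ps1": (-1.9, -1.9, -1.9, -1.9),   # signal 0.1, below background
            "L_ps2": (0, 0, 0.3, 0.3),
        }, noise_sd=0.01, seed=3)
        gm, log = collapse_probesets(matrix, {"L_ps1": "L", "L_ps2": "L"}, design,
                                     background_level=1.0)
        assert list(gm.index) == ["L"]
        dropped = log[log["rule"] == "below_background"]
        assert list(dropped["probeset"]) == ["L_ps1"]

    def test_missing_probe_map_entry_rejected(self):
        matrix, design = make_matrix({"X_ps1": (0, 0, 0, 0)}, seed=4)
        with pytest.raises(ValueError, match="probe_map missing"):
            collapse_probesets(matrix, {}, design)

    def test_planted_opposite_pairs_absent_from_bundle_collapse(self, small_bundle):
        gm, log = collapse_probesets(small_bundle.expression, small_bundle.probe_map,
                                     small_bundle.design)
        excluded = set(log.loc[log["rule"] == "opposite_directions", "gene"])
        assert excluded.isdisjoint(set(gm.index))


class TestDifferentialResponse:
    def test_zero_variance_gene_flagged_excluded(self):
        matrix, design = make_matrix({"Z_ps1": (0, 0, 0, 0)}, noise_sd=0.0)
        matrix.index = ["Z"]
        de = differential_response(matrix, design, "kd_0")
        assert bool(de.loc[0, "excluded"])

    def test_unknown_contrast_rejected(self):
        matrix, design = make_matrix({"A": (0, 0, 0, 0)})
        with pytest.raises(KeyError, match="unknown contrast"):
            differential_response(matrix, design, "nope")

    def test_power_on_planted_effects_matches_noncentral_t_theory(self):
        # planted 0.3 log10 knockdown effect, noise 0.1, 3 batches: the
        # two-factor batch-paired model (residual df = 6) has closed-form
        # power 1 - F_nct(t_crit; 6, ncp) + F_nct(-t_crit; 6, ncp)
        from scipy import stats as sps
        crit = sps.t.ppf(0.975, 6)
        ncp = 0.3 / (0.1 * np.sqrt(2 / 3))
        theory = 1 - sps.nct.cdf(crit, 6, ncp) + sps.nct.cdf(-crit, 6, ncp)
        hits, total = 0, 0
        for seed in range(25):
            effects = {f"g{i}": (0, 0, 0.3, 0.3) for i in range(40)}
            effects.update({f"null{i}": (0, 0, 0, 0) for i in range(160)})
            matrix, design = make_matrix(effects, noise_sd=0.1, seed=seed)
            de = differential_response(matrix, design, "kd_0").set_index("gene")
            planted = [g for g in de.index if g.startswith("g")]
            hits += int((de.loc[planted, "p"] < 0.05).sum())
            total += len(planted)
        empirical = hits / total
        assert empirical >= 0.8
        assert abs(empirical - theory) < 0.04

    def test_false_discovery_control_on_nulls(self):
        # declared positives at q<0.1 should be mostly planted, not null
        false_hits, declared = 0, 0
        for seed in range(25):
            effects = {f"g{i}": (0, 0, 0.4, 0.4) for i in range(50)}
            effects.update({f"null{i}": (0, 0, 0, 0) for i in range(150)})
            matrix, design = make_matrix(effects, noise_sd=0.1, seed=100 + seed)
            de = differential_response(matrix, design, "kd_0")
            sig = de[(de["q"] < 0.1) & (de["p"] < 0.05)]
            declared += len(sig)
            false_hits += int(sig["gene"].str.startswith("null").sum())
        assert declared > 0
        assert false_hits / declared <= 0.15

    def test_row_and_column_order_invariance(self):
        effects = {f"g{i}": tuple(np.random.default_rng(i).normal(0, 0.3, 4))
                   for i in range(30)}
        matrix, design = make_matrix(effects, noise_sd=0.05, seed=8)
        de1 = differential_response(matrix, design, "kd_30").set_index("gene")
        shuffled = matrix.sample(frac=1, axis=0, random_state=1).sample(
            frac=1, axis=1, random_state=2)
        de2 = differential_response(shuffled, design, "kd_30").set_index("gene")
        pd.testing.assert_frame_equal(de1.sort_index(), de2.sort_index())


class TestFilterRegulated:
    def frame(self, rows):
        return pd.DataFrame(rows, columns=["gene", "p", "q", "direction",
                                           "excluded", "effect"])

    def test_both_thresholds_required(self):
        de = self.frame([("a", 0.04, 0.12, "up", False, 1.0),
                         ("b", 0.01, 0.05, "down", False, -1.0)])
        reg = filter_regulated(de)
        assert reg == {"up": [], "down": ["b"]}

    def test_up_down_partition_no_duplicates(self):
        de = self.frame([(f"g{i}", 0.001, 0.001, "up" if i % 2 else "down",
                          False, 1.0) for i in range(20)])
        reg = filter_regulated(de)
        assert set(reg["up"]).isdisjoint(reg["down"])
        assert len(reg["up"]) + len(reg["down"]) == 20


class TestZTransform:
    def test_flat_profile_excluded(self):
        matrix, design = make_matrix({"F": (0, 0, 0, 0)})
        matrix.index = ["F"]
        assert len(z_transform_profiles(matrix, design)) == 0

    def test_hand_computed_values(self):
        matrix, design = make_matrix({"G": (1, 2, 3, 4)}, baseline=0.0)
        matrix.index = ["G"]
        z = z_transform_profiles(matrix, design)
        np.testing.assert_allclose(
            z.loc["G"].to_numpy(),
            [-1.161895, -0.387298, 0.387298, 1.161895], atol=1e-5)

    def test_profiles_are_standardised(self, small_bundle):
        gm, _ = collapse_probesets(small_bundle.expression, small_bundle.probe_map,
                                   small_bundle.design)
        z = z_transform_profiles(gm, small_bundle.design)
        np.testing.assert_allclose(z.mean(axis=1), 0, atol=1e-9)
        np.testing.assert_allclose(z.std(axis=1, ddof=1), 1, atol=1e-9)

    def test_condition_permutation_equivariance(self):
        rng = np.random.default_rng(11)
        effects = {f"g{i}": tuple(rng.normal(0, 0.5, 4)) for i in range(10)}
        matrix, design = make_matrix(effects, noise_sd=0.0)
        z = z_transform_profiles(matrix, design)
        # permuting the four condition blocks permutes z columns identically
        perm = [2, 0, 3, 1]
        permuted_effects = {g: tuple(np.array(v)[perm]) for g, v in effects.items()}
        m2, d2 = make_matrix(permuted_effects, noise_sd=0.0)
        z2 = z_transform_profiles(m2, d2)
        np.testing.assert_allclose(z.to_numpy()[:, perm], z2.to_numpy(), atol=1e-12)


class TestKMeans:
    def test_exactly_repeated_archetypes_fully_recovered(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=4)
        b = rng.normal(size=4) + 5
        X = pd.DataFrame([a] * 10 + [b] * 10,
                         index=[f"g{i}" for i in range(20)])
        asn = kmeans_cluster(X, k=2, seed=1)
        truth = [0] * 10 + [1] * 10
        assert adjusted_rand_score(truth, [asn.labels[g] for g in X.index]) == 1.0

    def test_requires_at_least_k_profiles(self):
        X = pd.DataFrame(np.eye(4), index=list("abcd"))
        with pytest.raises(ValueError, match="need >= 8"):
            kmeans_cluster(X, k=8)

    def test_deterministic_per_seed_and_no_empty_cluster(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(100, 4)),
                         index=[f"g{i}" for i in range(100)])
        a1 = kmeans_cluster(X, k=8, seed=42)
        a2 = kmeans_cluster(X, k=8, seed=42)
        assert a1.labels == a2.labels
        assert all(v > 0 for v in a1.sizes().values())

    def test_noiseless_bundle_recovers_planted_clusters_exactly(self, small_config):
        import dataclasses
        cfg = dataclasses.replace(small_config, noise_sd=0.0, probe_offset_sd=0.0,
                                  low_probe_frac=0.0, opposite_pair_frac=0.0,
                                  probeset_count_dist={1: 1.0})
        bundle = generate_bundle(cfg)
        gm, _ = collapse_probesets(bundle.expression, bundle.probe_map,
                                   bundle.design, background_level=0.0)
        genes = [g for g in gm.index if g in bundle.truth.gene_cluster]
        z = z_transform_profiles(gm.loc[genes], bundle.design)
        asn = kmeans_cluster(z, k=8, seed=3)
        truth = [bundle.truth.gene_cluster[g] for g in z.index]
        pred = [asn.labels[g] for g in z.index]
        assert adjusted_rand_score(truth, pred) == pytest.approx(1.0)


class TestModeAssociations:
    def test_cluster_mode_margins_conserved(self, small_bundle):
        gm, _ = collapse_probesets(small_bundle.expression, small_bundle.probe_map,
                                   small_bundle.design)
        mode = small_bundle.truth.mode_by_gene()
        genes = [g for g in gm.index if g in mode]
        z = z_transform_profiles(gm.loc[genes], small_bundle.design)
        asn = kmeans_cluster(z, k=8, seed=1)
        df = cluster_mode_association(asn, mode)
        labelled = [g for g in asn.labels if g in mode]
        assert (df["n"].sum()) == len(labelled)

    def test_direction_mode_counts_and_degenerate_table(self):
        mode = {"a": "unique", "b": "unique", "c": "redundant"}
        counts, res = direction_mode_split({"up": [], "down": ["a", "b"]}, mode)
        assert counts.loc["down", "unique"] == 2
        assert res.test_used == "fisher"
        assert res.p == pytest.approx(1.0)

    def test_planted_direction_mode_coupling_detected(self):
        rng = np.random.default_rng(7)
        mode, up, down = {}, [], []
        for i in range(200):
            g = f"g{i}"
            if i % 2:
                mode[g] = "unique"
                (down if rng.random() < 0.85 else up).append(g)
            else:
                mode[g] = "redundant"
                (up if rng.random() < 0.85 else down).append(g)
        _, res = direction_mode_split({"up": up, "down": down}, mode)
        assert res.p < 1e-4
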