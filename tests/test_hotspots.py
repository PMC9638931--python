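"""Hotspot calling, normalization, sharing and expansion statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pemseq import (
    HotspotParams,
    annotate_hotspot_genes,
    call_hotspots,
    category_proportions,
    expansion_stats,
    hotspots_from_molecules,
    junction_track,
    normalize_to_editing_events,
    shared_sites,
    viral_profile,
)


def _track(counts, ref="chr1", start=0):
    pos = np.flatnonzero(counts)
    return pd.DataFrame({"ref": ref, "pos": pos + start,
                         "count": np.asarray(counts)[pos]})


def _brute_force_calls(counts, cutoff=5, min_length=1, ref="chr1", start=0):
    calls, run = [], None
    for i, c in enumerate(list(counts) + [0]):
        if c >= cutoff:
            if run is None:
                run = [i, 0]
            run[1] += c
        elif run is not None:
            if i - run[0] >= min_length:
                calls.append((ref, start + run[0], start + i, run[1]))
            run = None
    return pd.DataFrame(calls, columns=["ref", "start", "end",
                                        "normalized_junctions"])


class TestCallHotspots:
    def test_single_position_at_cutoff_is_a_1bp_hotspot(self):
        counts = np.zeros(100, dtype=int)
        counts[40] = 5
        calls = call_hotspots(_track(counts))
        assert len(calls) == 1
        assert tuple(calls.iloc[0]) == ("chr1", 40, 41, 5)

    def test_below_cutoff_calls_nothing(self):
        counts = np.full(200, 4)
        assert call_hotspots(_track(counts)).empty

    @pytest.mark.parametrize("min_length", [1, 3])
    def test_matches_brute_force_on_random_tracks(self, min_length):
        rng = np.random.default_rng(42)
        for _ in range(40):
            counts = rng.choice([0, 1, 2, 4, 5, 6, 9],
                                p=[0.55, 0.15, 0.1, 0.08, 0.06, 0.04, 0.02],
                                size=2_000)
            params = HotspotParams(min_length=min_length)
            got = call_hotspots(_track(counts), params)
            exp = _brute_force_calls(counts, min_length=min_length)
            pd.testing.assert_frame_equal(got.reset_index(drop=True), exp)


class TestNormalization:
    def _events(self, n, n_tr, seed=0):
        cls = np.array(["small_deletion"] * (n - n_tr) + ["translocation"] * n_tr)
        rng = np.random.default_rng(seed)
        rng.shuffle(cls)
        return pd.DataFrame({
            "event_class": cls,
            "prey_ref": "chr2",
            "prey_pos": np.arange(n),
            "prey_strand": "+",
        })

    def test_identical_samples_pass_through(self):
        a, b = self._events(500, 5), self._events(500, 5, seed=1)
        cohort = normalize_to_editing_events([a, b], seed=3)
        assert cohort.target_event_count == 500
        assert all(len(s) == 500 for s in cohort.samples)

    def test_subsample_is_a_subset_and_seeded(self):
        a, b = self._events(900, 9), self._events(500, 5)
        c1 = normalize_to_editing_events([a, b], seed=7)
        c2 = normalize_to_editing_events([a, b], seed=7)
        pd.testing.assert_frame_equal(c1.samples[0], c2.samples[0])
        keys = set(map(tuple, a[["prey_pos"]].itertuples(index=False)))
        assert all((p,) in keys for p in c1.samples[0]["prey_pos"])
        assert len(c1.samples[0]) == 500

    def test_translocations_scale_hypergeometrically(self):
        # the in-paper depths: 167 611 events with 1682 translocations
        # normalized down to 139 085
        N, K, n = 167_611, 1_682, 139_085
        a = self._events(N, K)
        b = self._events(n, 10)
        cohort = normalize_to_editing_events([a, b], seed=11)
        got = int((cohort.samples[0]["event_class"] == "translocation").sum())
        expected = K * n / N
        sd = np.sqrt(stats.hypergeom(N, K, n).var())
        assert abs(got - expected) <= 4 * sd


class TestGeneAnnotation:
    def test_in_gene_flags(self, genes):
        calls = pd.DataFrame(
            [("chr2", 60_000, 60_001, 7), ("chr2", 150_000, 150_001, 5)],
            columns=["ref", "start", "end", "normalized_junctions"],
        )
        out = annotate_hotspot_genes(calls, genes)
        assert list(out["in_gene"]) == [True, False]
        assert out["gene"].iloc[0] == "GeneB1"

    def test_uniform_hits_fall_in_genes_at_genomic_density(self, ref, genes):
        rng = np.random.default_rng(19)
        gene_bp = int((genes.genes["end"] - genes.genes["start"]).sum())
        genome_bp = sum(len(s) for s in ref.chromosomes.values())
        p = gene_bp / genome_bp
        n = 2_000
        chroms = rng.choice(["chr1", "chr2"], size=n)
        pos = rng.integers(0, 2_000_000, size=n)
        calls = pd.DataFrame({"ref": chroms, "start": pos, "end": pos + 1,
                              "normalized_junctions": 5})
        out = annotate_hotspot_genes(calls, genes)
        frac = out["in_gene"].mean()
        assert abs(frac - p) <= 3 * np.sqrt(p * (1 - p) / n)


class TestExpansionStats:
    def test_clonal_site_has_uniform_orientation(self):
        mol = pd.DataFrame({
            "prey_ref": "chr2", "prey_pos": 777, "prey_strand": "+",
            "rmb": [f"AAAA{i:010d}".replace("0", "A").replace("1", "C")
                    for i in range(20)],
        })
        site, summary = expansion_stats(mol)
        assert site["orientation_uniformity"].iloc[0] == 1.0
        assert summary["mean_copies_per_site"] == 20

    def test_background_site_mixes_orientations(self):
        rng = np.random.default_rng(2)
        mol = pd.DataFrame({
            "prey_ref": "chr2", "prey_pos": 777,
            "prey_strand": rng.choice(["+", "-"], size=100),
            "rmb": [f"r{i}" for i in range(100)],
        })
        site, _ = expansion_stats(mol)
        assert site["orientation_uniformity"].iloc[0] < 1.0

    def test_expansion_raises_mean_copies(self, ref, target):
        from pemseq import preset_cohort, simulate_molecules
        from pemseq.simulate import molecules_from_truth

        def mean_copies(preset, seed):
            cfg = preset_cohort(preset, seed=seed, n_molecules=20_000)
            truth = simulate_molecules(cfg, ref, target)
            mol = molecules_from_truth(truth)
            tr = mol[(truth["class"] == "translocation").to_numpy()]
            _, summary = expansion_stats(tr)
            return summary["mean_copies_per_site"]

        assert mean_copies("inflammatory", 4) > mean_copies("activated", 4)


class TestSharedSites:
    def test_in_paper_sharing_fraction(self):
        # 146 distinct viral integration sites across four samples, 10 of
        # them seen in at least two -> 6.85%
        a = [("RV", i) for i in range(146)]
        b = [("RV", i) for i in range(10)]
        c = [("RV", 0)]
        d = [("RV", 1)]
        total, shared, pct = shared_sites([a, b, c, d])
        assert (total, shared) == (146, 10)
        assert pct == pytest.approx(6.849, abs=0.01)
        assert pct < 7.0

    def test_disjoint_and_identical_lists(self):
        a = [("chr1", 1), ("chr1", 2)]
        b = [("chr1", 3)]
        assert shared_sites([a, b])[2] == 0.0
        assert shared_sites([a, list(a)])[2] == 100.0

    def test_requires_two_samples(self):
        with pytest.raises(ValueError):
            shared_sites([[("chr1", 1)]])

    def test_symmetric_under_sample_permutation(self):
        rng = np.random.default_rng(23)
        lists = [
            [("chr1", int(p)) for p in rng.integers(0, 50, size=30)]
            for _ in range(4)
        ]
        base = shared_sites(lists)
        for perm in ([3, 2, 1, 0], [1, 3, 0, 2]):
            assert shared_sites([lists[i] for i in perm]) == base


class TestViralProfile:
    def _mol(self, positions, strands=None):
        return pd.DataFrame({
            "prey_ref": "RV",
            "prey_pos": positions,
            "prey_strand": strands if strands is not None else "+",
        })

    def test_dominant_clone_fraction(self, ref):
        # one expanded integration near the 3'LTR boundary carrying 89.1%
        n_clone, n_bg = 891, 109
        pos = [2_390] * n_clone + list(range(500, 500 + n_bg))
        _, elements, props = viral_profile(self._mol(pos), ref)
        assert props["fraction"].iloc[0] == pytest.approx(0.891, abs=1e-9)
        assert props["fraction"].sum() == pytest.approx(1.0)

    def test_ltr_positions_flagged_ambiguous(self, ref):
        track, _, _ = viral_profile(self._mol([100, 1_000]), ref)
        flags = dict(zip(track["pos"], track["ambiguous_ltr"]))
        assert flags[100] and not flags[1_000]

    def test_element_totals(self, ref):
        _, elements, _ = viral_profile(self._mol([10, 500, 600, 2_500]), ref)
        assert elements == {"5LTR": 1, "payload": 2, "3LTR": 1}

    def test_uniform_integrations_have_no_outlier_position(self, ref):
        rng = np.random.default_rng(29)
        L = len(ref.viral_seq)
        n = 1_000
        track, _, _ = viral_profile(self._mol(rng.integers(0, L, size=n)), ref)
        # order-statistic bound on the max of L approx-Poisson(n/L) counts
        lam = n / L
        k = 1
        while L * stats.poisson.sf(k, lam) > 0.01:
            k += 1
        assert track["count"].max() <= k


class TestCategoryProportions:
    def test_clone_proportion_recovered(self):
        mol = pd.DataFrame({
            "prey_ref": "chr1",
            "prey_pos": [1_500] * 372 + list(range(628)),
            "prey_strand": "+",
            "bait_end": 1_000,
            "insertion": "",
        })
        tab = category_proportions(mol)
        assert tab["fraction"].iloc[0] == pytest.approx(0.372)
        assert tab["fraction"].sum() == pytest.approx(1.0)

    def test_all_unique_pool_is_flat(self):
        mol = pd.DataFrame({
            "prey_ref": "chr1", "prey_pos": range(50), "prey_strand": "+",
            "bait_end": 1_000, "insertion": "",
        })
        tab = category_proportions(mol)
        assert (tab["fraction"] == 1 / 50).all()

    def test_empty_class_gives_empty_table(self):
        assert category_proportions(pd.DataFrame(
            columns=["prey_ref", "prey_pos", "prey_strand", "bait_end",
                     "insertion"])).empty


class TestPresetHotspotBehaviour:
    def test_inflammatory_founders_become_hotspots_activated_none(
        self, ref, target, genes
    ):
        from pemseq import preset_cohort, simulate_molecules
        from pemseq.simulate import molecules_from_truth

        cfg = preset_cohort("inflammatory", seed=6, n_molecules=20_000)
        truth = simulate_molecules(cfg, ref, target)
        mol = molecules_from_truth(truth)
        tr = mol[(truth["class"] == "translocation").to_numpy()]
        calls = hotspots_from_molecules(tr, genes=genes)
        founder_sites = truth.loc[truth["clone_id"] != ".",
                                  ["prey_ref", "prey_pos"]].drop_duplicates()
        called = set(zip(calls["ref"], calls["start"]))
        for site in founder_sites.itertuples(index=False):
            assert (site.prey_ref, site.prey_pos) in called

        cfg_a = preset_cohort("activated", seed=6, n_molecules=20_000)
        truth_a = simulate_molecules(cfg_a, ref, target)
        mol_a = molecules_from_truth(truth_a)
        tr_a = mol_a[(truth_a["class"] == "translocation").to_numpy()]
        assert hotspots_from_molecules(tr_a).empty
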