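"""Outcome classification: rule boundaries, profiles, alleles, coding impact."""

import numpy as np
import pandas as pd
import pytest

from pemseq import (
    ClassificationThresholds,
    classify_event,
    classify_events,
    coding_impact,
    sample_profile,
    top_alleles,
)

CUT = 1_000_000


def _mol(prey_ref="chr1", prey_pos=CUT, prey_strand="+", bait_end=CUT,
         insertion="", is_perfect=False):
    return pd.DataFrame(
        [{
            "bait_chrom": "chr1", "bait_end": bait_end, "prey_ref": prey_ref,
            "prey_pos": prey_pos, "prey_strand": prey_strand,
            "insertion": insertion, "rmb": "A" * 14, "fragment_length": 350,
            "read_support": 1, "is_perfect": is_perfect,
        }]
    )


def _cls(target, **kw):
    df = classify_events(_mol(**kw), target)
    return df["event_class"].iloc[0]


class TestRuleBoundaries:
    @pytest.mark.parametrize(
        "kw,expected",
        [
            (dict(prey_pos=CUT + 61), "small_deletion"),       # the 61-bp clone
            (dict(prey_pos=CUT + 100), "small_deletion"),      # <=100 inclusive
            (dict(prey_pos=CUT + 101), "large_deletion"),
            (dict(prey_pos=CUT + 500_000), "large_deletion"),  # at the bound
            (dict(prey_pos=CUT + 500_001), "translocation"),   # outside +-500 kb
            (dict(prey_pos=CUT - 600_000), "translocation"),
            (dict(prey_ref="chr2", prey_pos=300_000), "translocation"),
            (dict(prey_ref="RV", prey_pos=2_500), "viral_integration"),  # 3'LTR
            (dict(prey_pos=CUT + 50, prey_strand="-"), "translocation"),  # inversion-like
            (dict(insertion="T"), "insertion"),
            (dict(), "perfect"),
            (dict(prey_pos=CUT - 1), "insertion"),  # 1-bp tandem duplication
            (dict(prey_pos=CUT - 101), "translocation"),  # large duplication-like
        ],
    )
    def test_rule_table(self, target, kw, expected):
        assert _cls(target, **kw) == expected

    def test_scalar_and_vector_classifiers_agree(self, target):
        rng = np.random.default_rng(5)
        rows = _random_molecules(rng, 2_000)
        vec = classify_events(rows, target)["event_class"]
        for i, row in enumerate(rows.itertuples(index=False)):
            scalar = classify_event(row, target)["event_class"]
            assert scalar == vec.iloc[i]

    def test_agrees_with_brute_force_rule_table(self, target):
        rng = np.random.default_rng(8)
        rows = _random_molecules(rng, 3_000)
        got = classify_events(rows, target)["event_class"]
        expected = [_oracle(r, target) for r in rows.itertuples(index=False)]
        assert list(got) == expected


def _random_molecules(rng, n):
    """Random junction tuples straddling every rule boundary."""
    refs = rng.choice(["chr1", "chr2", "RV"], size=n, p=[0.6, 0.2, 0.2])
    pos = np.where(
        refs == "RV",
        rng.integers(0, 2800, n),
        CUT + rng.choice(
            [-600_000, -500_001, -500_000, -101, -100, -1, 0, 1, 61, 100, 101,
             1_000, 499_999, 500_000, 500_001, 600_000],
            size=n,
        ),
    )
    strands = rng.choice(["+", "-"], size=n, p=[0.8, 0.2])
    ins = rng.choice(["", "T", "ACGT"], size=n, p=[0.7, 0.2, 0.1])
    perfect = (refs == "chr1") & (pos == CUT) & (ins == "") & (strands == "+")
    return pd.DataFrame({
        "bait_chrom": "chr1", "bait_end": CUT, "prey_ref": refs,
        "prey_pos": pos, "prey_strand": strands, "insertion": ins,
        "rmb": "A" * 14, "fragment_length": 350, "read_support": 1,
        "is_perfect": perfect,
    })


def _oracle(m, target, small=100, bound=500_000):
    """Literal restatement of the classification rules, kept independent of
    the implementation's vectorised path."""
    if m.is_perfect:
        return "perfect"
    if m.prey_ref == "RV":
        return "viral_integration"
    if m.prey_ref != target.chromosome:
        return "translocation"
    if m.prey_strand != "+":
        return "translocation"
    if abs(m.prey_pos - target.cut_position) > bound:
        return "translocation"
    d = m.prey_pos - m.bait_end
    if d >= 1:
        return "small_deletion" if d <= small else "large_deletion"
    if d == 0:
        return "insertion" if m.insertion else "perfect"
    return "insertion" if -d <= small else "translocation"


class TestSampleProfile:
    def test_efficiency_arithmetic(self, target):
        rows = pd.concat(
            [_mol(prey_pos=CUT + 10)] * 95 + [_mol(is_perfect=True)] * 5,
            ignore_index=True,
        )
        profile = sample_profile(classify_events(rows, target))
        assert profile["editing_efficiency"] == pytest.approx(0.95)
        assert profile["class_counts"]["small_deletion"] == 95
        assert sum(profile["class_frequencies"].values()) == pytest.approx(1.0)

    def test_all_perfect_sample_is_flagged_not_nan(self, target):
        rows = pd.concat([_mol(is_perfect=True)] * 10, ignore_index=True)
        profile = sample_profile(classify_events(rows, target))
        assert profile["no_editing_events"]
        assert profile["editing_efficiency"] == 0.0
        assert all(v == 0.0 for v in profile["class_frequencies"].values())

    def test_empty_input_rejected(self, target):
        with pytest.raises(ValueError):
            sample_profile(classify_events(_mol().iloc[:0], target))

    def test_frequencies_invariant_under_permutation(self, target):
        rng = np.random.default_rng(3)
        rows = _random_molecules(rng, 500)
        p1 = sample_profile(classify_events(rows, target))
        shuffled = rows.sample(frac=1.0, random_state=1).reset_index(drop=True)
        p2 = sample_profile(classify_events(shuffled, target))
        assert p1["class_counts"] == p2["class_counts"]


class TestTopAlleles:
    def test_one_bp_t_insertion_dominates_simulated_insertions(self, ref, target):
        from pemseq import simulate_molecules
        from pemseq.simulate import SimulationConfig, molecules_from_truth

        mix = {"perfect": 0.05, "insertion": 0.9, "small_deletion": 0.05,
               "large_deletion": 0.0, "translocation": 0.0,
               "viral_integration": 0.0}
        cfg = SimulationConfig(n_molecules=2_000, seed=21, outcome_mix=mix,
                               pcr_duplication_rate=0.0)
        truth = simulate_molecules(cfg, ref, target)
        events = classify_events(molecules_from_truth(truth), target)
        top = top_alleles(events, 5)
        assert top["event_class"].iloc[0] == "insertion"
        assert "ins=T" in top["signature"].iloc[0]
        ins_events = events[events["event_class"] == "insertion"]
        assert top["count"].iloc[0] / len(ins_events) > 0.6

    def test_ties_break_lexicographically(self, target):
        rows = pd.concat(
            [_mol(prey_pos=CUT + 10)] * 3 + [_mol(prey_pos=CUT + 5)] * 3,
            ignore_index=True,
        )
        top = top_alleles(classify_events(rows, target), 2)
        assert list(top["count"]) == [3, 3]
        assert top["signature"].iloc[0] < top["signature"].iloc[1]

    def test_n_larger_than_distinct_returns_all(self, target):
        rows = pd.concat([_mol(prey_pos=CUT + 10), _mol(prey_pos=CUT + 20)],
                         ignore_index=True)
        assert len(top_alleles(classify_events(rows, target), 99)) == 2


class TestCodingImpact:
    def test_intronic_indels_have_no_impact(self, target, genes):
        rows = pd.concat([_mol(prey_pos=CUT + d) for d in (5, 10, 20, 40)],
                         ignore_index=True)
        assert coding_impact(classify_events(rows, target), genes, target) == 1.0

    def test_exon_spanning_deletion_counts(self, target, genes):
        # one deletion through the Myc second exon (cut+5000..cut+5800)
        rows = pd.concat(
            [_mol(prey_pos=CUT + 10)] * 9 + [_mol(prey_pos=CUT + 6_000)],
            ignore_index=True,
        )
        frac = coding_impact(classify_events(rows, target), genes, target)
        assert frac == pytest.approx(0.9)

    def test_translocation_scored_on_bait_side_only(self, target, genes):
        # partner locus inside a gene on chr2 does not count
        rows = _mol(prey_ref="chr2", prey_pos=110_000)
        assert coding_impact(classify_events(rows, target), genes, target) == 1.0


class TestThresholds:
    def test_threshold_invariants(self):
        with pytest.raises(ValueError):
            ClassificationThresholds(small_deletion_max=0)
        with pytest.raises(ValueError):
            ClassificationThresholds(translocation_bound=400_000)
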