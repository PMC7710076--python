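"""Binding-site search and amplification prediction vs brute-force oracles."""

import numpy as np
import pytest

from ednaqpcr.oligos import IUPAC_EXPANSION, Oligo, reverse_complement
from ednaqpcr.screen import (
    ScreenPolicy,
    find_binding_sites,
    mismatch_summary,
    predict_amplification,
)


def brute_force_sites(oligo_seq, subject, max_mm):
    """Sliding-window Hamming scan on both strands, pure Python."""
    hits = []
    L = len(oligo_seq)
    for strand, query in (("+", oligo_seq), ("-", reverse_complement(oligo_seq))):
        for start in range(len(subject) - L + 1):
            window = subject[start : start + L]
            miss = [
                i + 1
                for i, (q, s) in enumerate(zip(query, window))
                if q not in IUPAC_EXPANSION.get(s, set())
            ]
            if strand == "-":
                miss = sorted(L + 1 - p for p in miss)
            if len(miss) <= max_mm:
                hits.append((strand, start + 1, len(miss), tuple(miss)))
    return sorted(hits, key=lambda h: (h[2], h[1], h[0]))


def rng_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestFindBindingSites:
    oligo = Oligo("f", "GCCGCTCCATTAGATCACGA", "forward")

    def test_planted_exact_match(self):
        rng = np.random.default_rng(1)
        subject = rng_seq(rng, 40) + self.oligo.sequence + rng_seq(rng, 30)
        hits = find_binding_sites(self.oligo, subject, 0)
        assert len(hits) == 1
        h = hits[0]
        assert (h.strand, h.start, h.mismatches) == ("+", 41, 0)
        assert h.three_prime_match

    def test_planted_reverse_complement_on_minus_strand(self):
        rng = np.random.default_rng(2)
        subject = rng_seq(rng, 25) + reverse_complement(self.oligo.sequence) + rng_seq(rng, 10)
        hits = find_binding_sites(self.oligo, subject, 0)
        assert len(hits) == 1 and hits[0].strand == "-" and hits[0].start == 26

    def test_mismatch_positions_are_oligo_coordinates(self):
        # mutate oligo position 3 and plant on the minus strand
        mutated = list(self.oligo.sequence)
        mutated[2] = "T" if mutated[2] != "T" else "A"
        subject = "AAAA" + reverse_complement("".join(mutated)) + "TTTT"
        (hit,) = find_binding_sites(self.oligo, subject, 1)
        assert hit.mismatch_positions == (3,)
        assert hit.three_prime_match

    def test_terminal_mismatch_clears_three_prime_flag(self):
        mutated = self.oligo.sequence[:-1] + ("T" if self.oligo.sequence[-1] != "T" else "G")
        subject = "AAAA" + mutated + "TTTT"
        (hit,) = find_binding_sites(self.oligo, subject, 1)
        assert not hit.three_prime_match

    def test_subject_iupac_matches_permissively(self):
        subject = "AAAA" + self.oligo.sequence[:-1] + "N" + "TTTT"
        (hit,) = find_binding_sites(self.oligo, subject, 0)
        assert hit.mismatches == 0

    def test_oligo_longer_than_subject_is_empty(self):
        assert find_binding_sites(self.oligo, "ACGT", 5) == []

    def test_matches_brute_force_on_random_subjects(self):
        rng = np.random.default_rng(7)
        for _ in range(150):
            oligo = rng_seq(rng, int(rng.integers(12, 24)))
            subject = rng_seq(rng, int(rng.integers(30, 120)))
            budget = int(rng.integers(0, 7))
            got = [
                (h.strand, h.start, h.mismatches, h.mismatch_positions)
                for h in find_binding_sites(oligo, subject, budget)
            ]
            assert got == brute_force_sites(oligo, subject, budget)

    def test_strand_symmetry_under_subject_revcomp(self):
        rng = np.random.default_rng(9)
        oligo = rng_seq(rng, 18)
        subject = rng_seq(rng, 90)
        fwd = find_binding_sites(oligo, subject, 4)
        rev = find_binding_sites(oligo, reverse_complement(subject), 4)
        flipped = sorted(
            ("+-"[h.strand == "+"], len(subject) - (h.start + 18 - 1) + 1, h.mismatches)
            for h in rev
        )
        assert sorted((h.strand, h.start, h.mismatches) for h in fwd) == flipped


def build_subject(assay, f_mm=0, r_mm=0, p_mm=0, spacer1=25, spacer2=25, seed=3):
    """Subject with a planted F|P|revcomp(R) cassette and known mismatches."""
    rng = np.random.default_rng(seed)

    def mutate(seq, k):
        seq = list(seq)
        for pos in rng.choice(len(seq), size=k, replace=False):
            seq[pos] = [b for b in "ACGT" if b != seq[pos]][rng.integers(3)]
        return "".join(seq)

    return (
        rng_seq(rng, 30)
        + mutate(assay.forward.sequence, f_mm)
        + rng_seq(rng, spacer1)
        + mutate(assay.probe.sequence, p_mm)
        + rng_seq(rng, spacer2)
        + mutate(reverse_complement(assay.reverse.sequence), r_mm)
        + rng_seq(rng, 30)
    )


class TestPredictAmplification:
    def test_clean_cassette_positive_with_expected_product(self, humpback):
        subject = build_subject(humpback)
        pred = predict_amplification(humpback, subject, ScreenPolicy())
        expected = len(humpback.forward) + 25 + len(humpback.probe) + 25 + len(humpback.reverse)
        assert pred.positive and pred.product_length == expected
        assert pred.forward.mismatches == pred.reverse.mismatches == pred.probe.mismatches == 0

    def test_budget_exceeded_in_forward_is_negative_with_reason(self, humpback):
        subject = build_subject(humpback, f_mm=6)
        pred = predict_amplification(humpback, subject, ScreenPolicy())
        assert not pred.positive and "forward" in pred.reason

    def test_zero_budget_equals_exact_substring_search(self, humpback):
        rng = np.random.default_rng(21)
        policy = ScreenPolicy(
            max_mismatches={"forward": 0, "reverse": 0, "probe": 0},
            product_size=(60, 250),
        )
        f, p = humpback.forward.sequence, humpback.probe.sequence
        r_rc = reverse_complement(humpback.reverse.sequence)
        for i in range(300):
            if rng.random() < 0.5:
                subject = build_subject(
                    humpback,
                    f_mm=int(rng.integers(0, 2)),
                    r_mm=int(rng.integers(0, 2)),
                    p_mm=int(rng.integers(0, 2)),
                    seed=1000 + i,
                )
            else:
                subject = rng_seq(rng, 200)
            pred = predict_amplification(humpback, subject, policy)
            fi = subject.find(f)
            ri = subject.find(r_rc)
            expected = (
                fi >= 0
                and ri >= 0
                and ri > fi + len(f) - 1
                and 60 <= (ri + len(r_rc) - 1) - fi + 1 <= 250
                and fi + len(f) - 1 < subject.find(p, fi + len(f)) < ri
                if subject.find(p, fi + len(f)) >= 0
                else False
            )
            assert pred.positive == bool(expected), subject

    def test_monotone_in_mismatch_budget(self, humpback):
        subject = build_subject(humpback, f_mm=3, r_mm=2, p_mm=4)
        for low, high in ((0, 3), (3, 4), (4, 6)):
            lo = ScreenPolicy(max_mismatches=dict.fromkeys(("forward", "reverse", "probe"), low))
            hi = ScreenPolicy(max_mismatches=dict.fromkeys(("forward", "reverse", "probe"), high))
            p_lo = predict_amplification(humpback, subject, lo)
            p_hi = predict_amplification(humpback, subject, hi)
            assert not (p_lo.positive and not p_hi.positive)

    def test_product_out_of_range_reason(self, humpback):
        subject = build_subject(humpback, spacer1=5, spacer2=5)
        policy = ScreenPolicy(product_size=(150, 200))
        pred = predict_amplification(humpback, subject, policy)
        assert not pred.positive and pred.reason == "product out of range"

    def test_wrong_orientation_reason(self, humpback):
        rng = np.random.default_rng(5)
        # R cassette before F: no F(+) upstream of R(-)
        subject = (
            rng_seq(rng, 20)
            + reverse_complement(humpback.reverse.sequence)
            + rng_seq(rng, 10)
            + humpback.forward.sequence
            + rng_seq(rng, 20)
        )
        pred = predict_amplification(humpback, subject, ScreenPolicy(product_size=(10, 400)))
        assert not pred.positive and pred.reason == "wrong orientation"


class TestMismatchSummary:
    def test_identical_targets_mean_zero(self, humpback):
        subject = build_subject(humpback)
        df = mismatch_summary(humpback, {"target": [(f"t{i}", subject) for i in range(3)]})
        row = df.iloc[0]
        assert row["mean_mismatches_forward"] == 0.0
        assert row["mean_mismatches_reverse"] == 0.0
        assert row["mean_mismatches_probe"] == 0.0

    def test_planted_mismatch_arithmetic(self, humpback):
        seqs = [(f"s{k}", build_subject(humpback, f_mm=k, seed=50 + k)) for k in (1, 2, 3)]
        df = mismatch_summary(humpback, {"grp": seqs})
        assert df.iloc[0]["mean_mismatches_forward"] == pytest.approx(2.0)

    def test_no_hit_counted_separately(self, humpback):
        rng = np.random.default_rng(77)
        df = mismatch_summary(
            humpback, {"bg": [("b1", rng_seq(rng, 150)), ("b2", rng_seq(rng, 150))]}, cap=3
        )
        row = df.iloc[0]
        assert row["no_hit_forward"] == 2 and np.isnan(row["mean_mismatches_forward"])

    def test_matches_brute_force_recomputation(self, humpback):
        rng = np.random.default_rng(13)
        seqs = [
            (f"x{i}", build_subject(humpback, f_mm=int(rng.integers(0, 4)), seed=900 + i))
            for i in range(5)
        ]
        df = mismatch_summary(humpback, {"g": seqs}, cap=5)
        for role in ("forward", "reverse", "probe"):
            oligo = getattr(humpback, role).sequence
            mins = []
            for _, subject in seqs:
                hits = brute_force_sites(oligo, subject, 5)
                if hits:
                    mins.append(min(h[2] for h in hits))
            assert df.iloc[0][f"mean_mismatches_{role}"] == pytest.approx(np.mean(mins))

    def test_empty_group_rejected(self, humpback):
        with pytest.raises(ValueError, match="empty"):
            mismatch_summary(humpback, {"g": []})
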