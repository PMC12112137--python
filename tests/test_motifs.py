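"""Motif matching: mismatch counting, DnaA-box detection, promoter scans.

The scanners are checked against independent brute-force oracles
(conftest) on every instance up to 2 kb used here.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from arrascan import (
    ContractError,
    ScanParams,
    count_mismatches,
    find_dnaa_boxes,
    scan_promoters,
)
from arrascan.sequences import revcomp
from arrascan.simulate import generate_locus
from arrascan.genome_io import extract_target_region

from conftest import hamming, oracle_boxes, oracle_promoters

DNA = st.text(alphabet="ACGT", min_size=0, max_size=40)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


class TestCountMismatches:
    @pytest.mark.parametrize(
        "observed,consensus,expected",
        [
            ("TATAGT", "TATAAT", 1),   # B. licheniformis −10 vs consensus
            ("ATGAAA", "TTGACA", 2),   # B. licheniformis −35 vs consensus
            ("TACACA", "TTGACA", 2),   # B. subtilis −35 vs consensus
            ("TATAAT", "TATAAT", 0),
            ("GGGGGG", "TATAAT", 6),   # promoter-ablating substitution
            ("TATANT", "TATAAT", 1),   # N is always a mismatch
            ("NNNNNN", "NNNNNN", 6),
        ],
    )
    def test_worked_examples(self, observed, consensus, expected):
        assert count_mismatches(observed, consensus) == expected

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ContractError):
            count_mismatches("TATAAT", "TATAATA")

    @settings(max_examples=200, derandomize=True)
    @given(DNA, DNA)
    def test_symmetric_and_bounded(self, a, b):
        n = min(len(a), len(b))
        a, b = a[:n], b[:n]
        d = count_mismatches(a, b)
        assert d == count_mismatches(b, a)
        assert 0 <= d <= n
        assert (d == 0) == (a == b)  # no N in the strategy alphabet


class TestFindDnaaBoxes:
    def _masked_background(self, seed: int, n: int, params: ScanParams) -> str:
        """A background with no window reaching min_box_matches (verified by
        the oracle, so the masking itself is independent of the scanner)."""
        rng = np.random.default_rng(seed)
        for _ in range(500):
            seq = random_dna(rng, n)
            if not oracle_boxes(seq, params.box_consensus, params.min_box_matches):
                return seq
        raise AssertionError("could not draw a box-free background")

    def test_planted_consensus_box(self):
        params = ScanParams()
        background = self._masked_background(0, 100, params)
        seq = background[:10] + params.box_consensus + background[19:]
        hits = find_dnaa_boxes(seq, params)
        assert len(hits) == 1
        hit = hits[0]
        assert (hit.start, hit.end, hit.orientation) == (10, 19, "+")
        assert hit.matches == 9 and hit.similarity == 1.0

    def test_planted_reverse_complement_box(self):
        params = ScanParams()
        background = self._masked_background(1, 100, params)
        seq = background[:10] + revcomp(params.box_consensus) + background[19:]
        hits = find_dnaa_boxes(seq, params)
        assert [(h.start, h.orientation) for h in hits] == [(10, "-")]
        assert hits[0].seq == revcomp(params.box_consensus)

    def test_region_shorter_than_box_is_empty(self):
        assert find_dnaa_boxes("ACGTACGT", ScanParams()) == []

    @pytest.mark.parametrize("seed,length", [(0, 50), (1, 137), (2, 300),
                                             (3, 991), (4, 2000)])
    def test_oracle_equivalence(self, seed, length):
        """Full hit list equals naive enumeration over every window and
        both orientations."""
        params = ScanParams()
        seq = random_dna(np.random.default_rng(seed), length)
        hits = find_dnaa_boxes(seq, params)
        assert [(h.start, h.orientation, h.matches) for h in hits] == \
            oracle_boxes(seq, params.box_consensus, params.min_box_matches)

    def test_oracle_equivalence_on_synthetic_region(self):
        params = ScanParams()
        record, _ = generate_locus("III", seed=13)
        seq = extract_target_region(record).sequence
        hits = find_dnaa_boxes(seq, params)
        assert [(h.start, h.orientation, h.matches) for h in hits] == \
            oracle_boxes(seq, params.box_consensus, params.min_box_matches)

    def test_reverse_complement_involution(self):
        """Scanning the reverse complement mirrors coordinates and flips
        orientations."""
        params = ScanParams()
        seq = random_dna(np.random.default_rng(7), 400)
        forward = find_dnaa_boxes(seq, params)
        backward = find_dnaa_boxes(revcomp(seq), params)
        n, k = len(seq), params.box_length
        mirrored = sorted(
            (n - h.end, "-" if h.orientation == "+" else "+", h.matches)
            for h in forward
        )
        assert mirrored == [(h.start, h.orientation, h.matches) for h in backward]

    def test_threshold_monotonicity(self):
        """Raising min_box_matches never adds hits."""
        seq = random_dna(np.random.default_rng(11), 600)
        previous = None
        for threshold in (5, 6, 7, 8, 9):
            params = ScanParams(min_box_matches=threshold)
            hits = {(h.start, h.orientation) for h in find_dnaa_boxes(seq, params)}
            if previous is not None:
                assert hits <= previous
            previous = hits


class TestScanPromoters:
    def test_planted_promoter_ranks_first(self):
        """A planted consensus −10 with a 2-mismatch −35 at a 16-bp spacer
        is recovered as the top candidate."""
        record, truth = generate_locus("I", seed=1)
        region = extract_target_region(record)
        candidates = scan_promoters(region)
        assert candidates, "planted promoter not found"
        top = candidates[0]
        assert (top.mm10, top.mm35, top.spacer) == (0, 2, 16)
        assert top.m10_start == truth.planted_m10_start
        assert top.m35_start == truth.planted_m35_start
        assert top.m10_seq == "TATAAT"

    def test_minus10_ablation_removes_candidate(self):
        """Replacing the −10 with GGGGGG (6 mismatches) silences the scan
        at default budgets."""
        record, truth = generate_locus("I", seed=1)
        seq = extract_target_region(record).sequence
        m10 = truth.planted_m10_start
        ablated = seq[:m10] + "GGGGGG" + seq[m10 + 6:]
        assert scan_promoters(ablated) == []

    def test_predicted_tss_offset(self):
        record, truth = generate_locus("I", seed=2)
        region = extract_target_region(record)
        top = scan_promoters(region)[0]
        # default: 7 nt from the 3' end of the −10 (inclusive convention)
        assert top.predicted_tss == truth.planted_m10_start + 6 + 7 - 1

    @pytest.mark.parametrize("seed,length", [(5, 60), (6, 250), (7, 777),
                                             (8, 2000)])
    def test_oracle_equivalence(self, seed, length):
        params = ScanParams(max_mm10=2, max_mm35=3)  # budgets loose enough to hit
        seq = random_dna(np.random.default_rng(seed), length)
        got = {
            (c.m35_start, c.m10_start, c.mm35, c.mm10, c.spacer)
            for c in scan_promoters(seq, params)
        }
        expected = oracle_promoters(
            seq, params.consensus_m10, params.consensus_m35,
            params.max_mm10, params.max_mm35, *params.spacer_range,
        )
        assert got == expected

    def test_sort_order_contract(self):
        """Candidates sort by total mismatches, then spacer distance from
        16, then leftmost −10; the ordering is deterministic."""
        seq = random_dna(np.random.default_rng(9), 1500)
        params = ScanParams(max_mm10=2, max_mm35=3)
        candidates = scan_promoters(seq, params)
        keys = [(c.mm10 + c.mm35, abs(c.spacer - 16), c.m10_start, c.m35_start)
                for c in candidates]
        assert keys == sorted(keys)
        assert scan_promoters(seq, params) == candidates

    def test_budget_monotonicity(self):
        """Lowering mismatch budgets never adds candidates."""
        seq = random_dna(np.random.default_rng(10), 1000)
        loose = {
            (c.m35_start, c.m10_start)
            for c in scan_promoters(seq, ScanParams(max_mm10=2, max_mm35=3))
        }
        tight = {
            (c.m35_start, c.m10_start)
            for c in scan_promoters(seq, ScanParams(max_mm10=1, max_mm35=2))
        }
        assert tight <= loose

    def test_short_region_yields_empty(self):
        assert scan_promoters("TATAAT") == []
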