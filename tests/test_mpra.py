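"""MPRA processing tests: read filters, UMI collapse, MRL, replicate
averaging, positional motif effects."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from utrforge.mpra import (
    FractionCountMatrix,
    FractionSpec,
    MRLRecord,
    ReadRecord,
    cluster_umis,
    collapse_umis,
    compute_mrl,
    default_fractions,
    filter_and_average_replicates,
    parse_and_filter_reads,
    positional_median_effect,
)


def make_matrix(counts, loads=None, with_free=False, replicate="rep1"):
    counts = np.atleast_2d(np.asarray(counts))
    n_loaded = counts.shape[1] - (1 if with_free else 0)
    fractions = []
    if with_free:
        fractions.append(FractionSpec("free", 0.0, is_free=True))
    loads = loads or list(range(1, n_loaded + 1))
    fractions += [FractionSpec(f"poly{r}", float(r)) for r in loads]
    variants = [f"v{i}" for i in range(counts.shape[0])]
    return FractionCountMatrix(variants, fractions, counts, replicate_id=replicate)


class TestReadFiltering:
    def _read(self, q=30.0, ts="ATTGGCCTGCGA"):
        return ReadRecord("ACGT", "AAAAAAAAAA", q, "poly1", ts_suffix=ts)

    def test_q_score_boundary(self):
        oligo = "ATTGGCCTGCGA"
        kept = list(parse_and_filter_reads(
            [self._read(q=24.0), self._read(q=25.0), self._read(q=25.1)], oligo))
        # strictly greater than 25
        assert [r.mean_q for r in kept] == [25.1]

    def test_ts_edit_distance_boundary(self):
        from utrforge.seqcore import edit_distance

        oligo = "ATTGGCCTGCGA"

        def mutate(positions):
            s = list(oligo)
            for p in positions:
                s[p] = {"A": "C", "T": "A", "G": "T", "C": "G"}[s[p]]
            return "".join(s)

        five = mutate([0, 2, 4, 6, 8])
        six = mutate([0, 2, 4, 6, 8, 10])
        assert edit_distance(five, oligo) == 5 and edit_distance(six, oligo) == 6
        kept = list(parse_and_filter_reads(
            [self._read(ts=five), self._read(ts=six), self._read(ts=oligo)], oligo))
        assert [r.ts_suffix for r in kept] == [five, oligo]

    def test_fixed_end_skips_ts_check(self):
        kept = list(parse_and_filter_reads([self._read(ts="GGGGGGGGGGGG")], None))
        assert len(kept) == 1

    def test_empty_input(self):
        assert list(parse_and_filter_reads([], "ATTGG")) == []


class TestUMICollapse:
    def test_identical_umis_merge(self):
        assert cluster_umis({"AAAAAAAAAA": 3}) == 1

    def test_hamming1_merges_into_abundant(self):
        assert cluster_umis({"AAAAAAAAAA": 5, "AAAAAAAAAT": 1}) == 1

    def test_distance2_stays_separate(self):
        assert cluster_umis({"AAAAAAAAAA": 5, "AAAAAAAATT": 1}) == 2

    def test_ragged_lengths_error(self):
        with pytest.raises(ValueError, match="ragged"):
            cluster_umis({"AAA": 1, "AAAA": 1})

    def test_brute_force_directional_oracle(self):
        # independent re-implementation: merge each UMI (desc count, lex)
        # into the best previously-placed Hamming-1 neighbour's cluster
        def oracle(counts):
            def hamming1(a, b):
                return len(a) == len(b) and sum(x != y for x, y in zip(a, b)) == 1
            order = sorted(counts, key=lambda u: (-counts[u], u))
            assignment = {}
            n = 0
            for u in order:
                candidates = [v for v in assignment if hamming1(u, v)]
                if candidates:
                    best = min(candidates, key=lambda v: (-counts[v], v))
                    assignment[u] = assignment[best]
                else:
                    assignment[u] = n
                    n += 1
            return n

        rng = np.random.default_rng(7)
        for _ in range(200):
            n_umis = int(rng.integers(1, 12))
            umis = ["".join("ACGT"[i] for i in rng.integers(0, 4, 4))
                    for _ in range(n_umis)]
            counts = {u: int(rng.integers(1, 20)) for u in umis}
            assert cluster_umis(counts) == oracle(counts)

    def test_collapse_to_matrix(self):
        fractions = default_fractions(2, include_free=False)
        reads = [
            ReadRecord("v1", "AAAA", 30, "poly1"),
            ReadRecord("v1", "AAAA", 30, "poly1"),
            ReadRecord("v1", "AAAT", 30, "poly1"),  # merges into AAAA
            ReadRecord("v1", "GGGG", 30, "poly2"),
            ReadRecord("v2", "CCCC", 30, "poly1"),
        ]
        m = collapse_umis(reads, fractions)
        assert m.variants == ["v1", "v2"]
        np.testing.assert_array_equal(m.counts, [[1, 1], [1, 0]])


class TestFastqRoundTrip:
    def test_write_read_filter_collapse_recovers_counts(self, tmp_path):
        from utrforge.mpra import read_paired_fastq, write_paired_fastq
        from utrforge.synthetic import FractionSimSpec, mpra_scenario, simulate_reads

        sc = mpra_scenario(20, 1, sim=FractionSimSpec(depth_per_fraction=400, seed=31),
                           seed=32)
        matrix = sc["matrices"][0]
        oligo = "ATTGGCCTGCGA"
        seq_of = {r.id: r.sequence for r in sc["records"]}
        reads = simulate_reads(matrix, seed=33, ts_oligo=oligo, sequences=seq_of)
        # one FASTQ pair per fraction, as a sequencing run would produce
        rebuilt_streams = []
        for frac in matrix.fractions:
            sub = [r for r in reads if r.fraction_id == frac.fraction_id]
            r1, r2 = tmp_path / f"{frac.fraction_id}_R1.fq", tmp_path / f"{frac.fraction_id}_R2.fq"
            write_paired_fastq(sub, r1, r2)
            rebuilt_streams.extend(parse_and_filter_reads(
                read_paired_fastq(r1, r2, frac.fraction_id, variable_length=25), oligo))
        rebuilt = collapse_umis(rebuilt_streams, matrix.fractions)
        # variable regions become the variant keys on the way back
        expected = {(seq_of[v], j): matrix.counts[i, j]
                    for i, v in enumerate(matrix.variants)
                    for j in range(len(matrix.fractions))}
        for i, v in enumerate(rebuilt.variants):
            for j in range(len(matrix.fractions)):
                assert rebuilt.counts[i, j] == expected[(v, j)]


class TestComputeMRL:
    def test_single_fraction_gives_its_load(self):
        # all of v0's counts sit in the load-3 fraction (a filler variant
        # keeps the other fraction libraries non-empty)
        m = make_matrix([[0, 0, 7], [10, 10, 10]])
        recs = compute_mrl(m)
        assert recs[0].mrl == pytest.approx(3.0)

    def test_hand_computed_example(self):
        # loads 1,2,3; fraction totals 100,100,200; variant counts 10,10,40
        counts = np.array([[10, 10, 40], [90, 90, 160]])
        recs = compute_mrl(make_matrix(counts))
        assert recs[0].mrl == pytest.approx((0.1 + 0.2 + 0.6) / 0.4)
        assert recs[0].mrl == pytest.approx(2.25)

    def test_brute_force_formula_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(1000):
            n_var = int(rng.integers(2, 8))
            n_frac = int(rng.integers(2, 6))
            counts = rng.integers(0, 50, size=(n_var, n_frac))
            counts[0, :] += 1  # keep fraction totals positive
            loads = np.arange(1, n_frac + 1)
            m = make_matrix(counts)
            got = {r.variant: r.mrl for r in compute_mrl(m)}
            totals = counts.sum(axis=0)
            for i in range(n_var):
                norm = counts[i] / totals
                if norm.sum() == 0:
                    assert f"v{i}" not in got
                    continue
                expected = float((norm * loads).sum() / norm.sum())
                assert got[f"v{i}"] == pytest.approx(expected, abs=1e-12)

    def test_per_fraction_rescaling_invariance(self):
        rng = np.random.default_rng(12)
        counts = rng.integers(1, 100, size=(6, 4))
        base = {r.variant: r.mrl for r in compute_mrl(make_matrix(counts))}
        scaled = counts.copy()
        scaled[:, 1] *= 10
        rescaled = {r.variant: r.mrl for r in compute_mrl(make_matrix(scaled))}
        for v in base:
            assert rescaled[v] == pytest.approx(base[v], abs=1e-12)

    def test_free_fraction_excluded_from_sums(self):
        with_free = make_matrix([[100, 0, 0, 7], [5, 8, 8, 8]], with_free=True)
        recs = compute_mrl(with_free)
        assert recs[0].mrl == pytest.approx(3.0)
        assert recs[0].total_reads == 107  # free counts still in depth

    def test_mrl_bounded_by_occupied_loads(self):
        rng = np.random.default_rng(13)
        counts = rng.integers(0, 30, size=(5, 6))
        counts[:, 0] += 1
        m = make_matrix(counts)
        for rec in compute_mrl(m):
            i = m.variants.index(rec.variant)
            occupied = np.flatnonzero(counts[i]) + 1
            assert occupied.min() <= rec.mrl <= occupied.max()

    def test_zero_total_fraction_is_error(self):
        with pytest.raises(ValueError, match="poly2"):
            compute_mrl(make_matrix([[5, 0, 3]]))


class TestReplicateAveraging:
    def test_min_reads_in_all_replicates(self):
        t1 = [MRLRecord("v1", 2.0, 150, "rep1"), MRLRecord("v2", 2.0, 150, "rep1")]
        t2 = [MRLRecord("v1", 3.0, 80, "rep2"), MRLRecord("v2", 3.0, 300, "rep2")]
        out = filter_and_average_replicates([t1, t2], min_reads=100)
        assert list(out.index) == ["v2"]

    def test_depth_weighted_mean(self):
        t1 = [MRLRecord("v1", 2.0, 100, "rep1")]
        t2 = [MRLRecord("v1", 3.0, 300, "rep2")]
        out = filter_and_average_replicates([t1, t2])
        assert out.loc["v1", "mrl"] == pytest.approx(2.75)
        assert out.loc["v1", "reads"] == 400

    def test_single_replicate_identity(self):
        t1 = [MRLRecord("v1", 2.5, 120, "rep1")]
        out = filter_and_average_replicates([t1])
        assert out.loc["v1", "mrl"] == pytest.approx(2.5)

    def test_replicate_order_invariance(self):
        rng = np.random.default_rng(3)
        tables = [
            [MRLRecord(f"v{i}", float(rng.uniform(1, 8)), int(rng.integers(100, 500)), f"rep{j}")
             for i in range(10)]
            for j in range(3)
        ]
        a = filter_and_average_replicates(tables)
        b = filter_and_average_replicates(tables[::-1])
        pd.testing.assert_frame_equal(a, b)


class TestPositionalMedianEffect:
    def test_identical_mrls_give_unit_median(self):
        table = pd.DataFrame({
            "sequence": ["ATGAAAA", "AATGAAA", "AAATGAA", "CCCCCCC"] * 20,
            "mrl": 4.0,
        })
        pred = lambda s, p: s[p : p + 3] == "ATG"
        out = positional_median_effect(table, pred, range(3), min_matches=10)
        assert np.allclose(out["normalized_median"].dropna(), 1.0)

    def test_sparse_positions_omitted(self):
        table = pd.DataFrame({"sequence": ["ATGAAAA"] * 60, "mrl": 4.0})
        pred = lambda s, p: s[p : p + 3] == "ATG"
        out = positional_median_effect(table, pred, [0, 1], min_matches=50)
        assert out.loc[0, "n"] == 60
        assert np.isfinite(out.loc[0, "normalized_median"])
        assert out.loc[1, "n"] == 0
        assert np.isnan(out.loc[1, "normalized_median"])

    def test_planted_positional_penalty_recovered(self):
        # MRL = 5 - delta(p) per planted motif occurrence at position p
        rng = np.random.default_rng(21)
        L = 25
        delta = 3.0 * np.arange(L - 2) / (L - 2)
        seqs, mrls = [], []
        for _ in range(4000):
            codes = rng.integers(0, 4, L)
            seq = "".join("ACGT"[c] for c in codes)
            value = 5.0
            for p in range(L - 2):
                if seq[p : p + 3] == "ATG":
                    value -= delta[p]
            seqs.append(seq)
            mrls.append(value + rng.normal(0, 0.1))
        table = pd.DataFrame({"sequence": seqs, "mrl": mrls})
        pred = lambda s, p: s[p : p + 3] == "ATG"
        out = positional_median_effect(table, pred, range(L - 2), min_matches=20)
        ok = out["normalized_median"].notna()
        rho = spearmanr(delta[ok.to_numpy()], out.loc[ok, "normalized_median"]).statistic
        assert rho <= -0.9

    def test_out_of_frame_uaug_hits_harder_than_in_frame(self):
        # planted-model library: at matched distal positions the
        # out-of-frame uAUG median should fall below the in-frame one
        from utrforge.synthetic import generate_library, ground_truth_mrl_batch

        records = generate_library(30_000, seed=41)
        table = pd.DataFrame({
            "sequence": [r.transcript for r in records],
            "mrl": ground_truth_mrl_batch(records, noise_seed=42),
        })
        offset = records[0].cds_offset
        pred = lambda s, p: s[p : p + 3] == "ATG"
        out = positional_median_effect(table, pred, range(10, 23), min_matches=30)
        med = out["normalized_median"]
        # the reading frame at a position is fixed by (offset - p) % 3, so
        # in-frame positions are compared with their out-of-frame neighbours
        checked = 0
        for p in range(11, 22):
            if (offset - p) % 3 == 0:
                assert med[p] > med[p - 1] and med[p] > med[p + 1]
                checked += 1
        assert checked >= 3

    def test_mann_whitney_pvalue_present(self):
        rng = np.random.default_rng(4)
        seqs = ["ATG" + "".join("ACGT"[c] for c in rng.integers(0, 4, 7)) for _ in range(60)]
        seqs += ["".join("CG"[c] for c in rng.integers(0, 2, 10)) for _ in range(60)]
        mrl = np.r_[rng.normal(2, 0.1, 60), rng.normal(5, 0.1, 60)]
        table = pd.DataFrame({"sequence": seqs, "mrl": mrl})
        pred = lambda s, p: s[p : p + 3] == "ATG"
        out = positional_median_effect(table, pred, [0], min_matches=10, with_pvalues=True)
        assert out.loc[0, "pvalue"] < 1e-6
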