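import itertools

import numpy as np
import pandas as pd
import pytest

from lncscape.motif_regulation import (
    BASES,
    PWM,
    exact_pvalues,
    integer_scores,
    presence_matrix,
    read_meme,
    regulatory_region,
    scan,
    scan_regions,
    tf_lnc_correlation,
    write_meme,
)
from lncscape.synthetic_data import make_sharp_pwm
from tests.conftest import make_gene


class TestRegulatoryRegion:
    def test_plus_strand_arithmetic(self):
        tx = make_gene("L", "chr1", [(10_000, 13_000)], "+").transcripts[0]
        r = regulatory_region(tx, chrom_length=1_000_000)
        assert (r.interval.start, r.interval.end) == (5_000, 11_000)

    def test_minus_strand_mirrors_plus(self):
        tx = make_gene("L", "chr1", [(7_000, 10_000)], "-").transcripts[0]
        r = regulatory_region(tx, chrom_length=1_000_000)
        assert (r.interval.start, r.interval.end) == (9_000, 15_000)
        # reflection symmetry: distances from the TSS match the + case
        plus = regulatory_region(
            make_gene("L", "chr1", [(10_000, 13_000)], "+").transcripts[0],
            1_000_000,
        )
        assert r.interval.end - 10_000 == 10_000 - plus.interval.start
        assert 10_000 - r.interval.start == plus.interval.end - 10_000

    def test_short_transcript_caps_downstream(self):
        tx = make_gene("L", "chr1", [(10_000, 10_600)], "+").transcripts[0]
        r = regulatory_region(tx, chrom_length=1_000_000)
        assert len(r.interval) == 5_600
        assert r.interval.end == 10_600

    def test_chromosome_edge_truncates_and_flags(self):
        tx = make_gene("L", "chr1", [(1_000, 4_000)], "+").transcripts[0]
        r = regulatory_region(tx, chrom_length=1_000_000)
        assert r.interval.start == 0
        assert r.truncated


class TestScan:
    def test_uniform_pwm_scores_zero(self):
        pwm = PWM("U", "U", np.full((4, 4), 0.25), np.full(4, 0.25))
        hits = scan(pwm, "ACGTACGTACGT", pseudocount=0.0)
        assert np.allclose(hits["score"], 0.0)

    def test_exact_p_equals_enumeration(self, rng):
        """DP survival function equals the 4^w enumeration for w <= 8."""
        for w, seed in [(3, 1), (5, 2), (8, 3)]:
            bg = rng.dirichlet(np.full(4, 5.0))
            probs = rng.dirichlet(np.full(4, 0.8), size=w).T
            pwm = PWM(f"M{w}", "TF", probs, bg)
            ints = integer_scores(pwm.log_odds(), 1e-3)
            sf, off = exact_pvalues(ints, pwm.background)
            tail_by_score = {}
            for word in itertools.product(range(4), repeat=w):
                s = int(sum(ints[b, j] for j, b in enumerate(word)))
                p = float(np.prod([bg[b] for b in word]))
                tail_by_score[s] = tail_by_score.get(s, 0.0) + p
            running = 0.0
            for s in sorted(tail_by_score, reverse=True):
                running += tail_by_score[s]
                assert sf[s - off] == pytest.approx(running, rel=1e-9, abs=1e-12)

    def test_planted_consensus_is_top_hit(self, rng):
        pwm = make_sharp_pwm("M", "TF", width=9, seed=4, sharpness=0.99)
        seq = "".join(rng.choice(list(BASES), 150))
        seq = seq[:42] + pwm.consensus() + seq[51:]
        hits = scan(pwm, seq)
        fwd = hits[hits["strand"] == "+"]
        top = fwd.loc[fwd["score"].idxmax()]
        assert top["offset"] == 42

    def test_reverse_complement_symmetry(self, rng):
        comp = str.maketrans("ACGT", "TGCA")
        pwm = make_sharp_pwm("M", "TF", width=6, seed=7)
        seq = "".join(rng.choice(list(BASES), 80))
        rc = seq.translate(comp)[::-1]
        fwd = scan(pwm, seq)
        rev = scan(pwm, rc)
        n = len(seq) - pwm.width
        for _, row in fwd.iterrows():
            mirrored = rev[
                (rev["offset"] == n - row["offset"])
                & (rev["strand"] != row["strand"])
            ]
            assert len(mirrored) == 1
            assert mirrored.iloc[0]["score"] == pytest.approx(row["score"])

    def test_p_monotone_in_score(self, rng):
        pwm = make_sharp_pwm("M", "TF", width=7, seed=9)
        seq = "".join(rng.choice(list(BASES), 300))
        hits = scan(pwm, seq).sort_values("score")
        assert (np.diff(hits["p"].values) <= 1e-12).all()

    def test_windows_with_n_skipped(self):
        pwm = make_sharp_pwm("M", "TF", width=4, seed=1)
        hits = scan(pwm, "ACGTNACGT")
        assert not any(1 <= o <= 4 for o in hits["offset"])

    def test_wider_than_sequence_gives_empty(self):
        pwm = make_sharp_pwm("M", "TF", width=8, seed=1)
        assert len(scan(pwm, "ACG")) == 0


class TestMeme:
    def test_round_trip(self, tmp_path, rng):
        pwms = [make_sharp_pwm(f"M{i}", f"TF{i}", width=5, seed=i) for i in range(3)]
        p = tmp_path / "motifs.meme"
        write_meme(pwms, p)
        back = read_meme(p)
        assert [m.motif_id for m in back] == [m.motif_id for m in pwms]
        for a, b in zip(pwms, back):
            assert np.allclose(a.probs, b.probs, atol=1e-5)
            assert a.width == b.width


class TestPresence:
    def test_counts_and_threshold(self):
        hits = pd.DataFrame(
            {
                "region_id": ["r1", "r1", "r2"],
                "tf_name": ["TFA", "TFA", "TFA"],
                "motif_id": ["m1", "m2", "m1"],
            }
        )
        mat, summary = presence_matrix(
            hits, ["r1", "r2", "r3"], ["TFA", "TFB"],
            deg_tfs={"TFA"}, highlight_threshold=1,
        )
        assert mat.loc["r1", "TFA"] == 1 and mat.loc["r3", "TFA"] == 0
        row = summary[summary["tf"] == "TFA"].iloc[0]
        assert row["n_regions"] == 2 and row["highlighted"] and row["is_deg"]
        assert (summary.set_index("tf")["n_regions"] == mat.sum(axis=0)).all()

    def test_no_hits_zero_matrix(self):
        mat, summary = presence_matrix(pd.DataFrame(), ["r1"], ["TFA"])
        assert mat.values.sum() == 0
        assert not summary["highlighted"].any()


class TestTfLncCorrelation:
    def test_planted_coregulation_masked_positive(self, rng):
        samples = [f"s{j}" for j in range(11)]
        z = rng.standard_normal(11)
        tf = pd.DataFrame([z + rng.normal(0, 0.2, 11)], index=["TF1"], columns=samples)
        lnc = pd.DataFrame([z + rng.normal(0, 0.2, 11)], index=["L1"], columns=samples)
        res = tf_lnc_correlation(tf, lnc)
        assert res["mask"].loc["TF1", "L1"]
        assert res["r"].loc["TF1", "L1"] > 0

    def test_self_correlation_is_one(self, rng):
        samples = [f"s{j}" for j in range(8)]
        prof = rng.standard_normal(8)
        tf = pd.DataFrame([prof], index=["TF1"], columns=samples)
        lnc = pd.DataFrame([prof], index=["L1"], columns=samples)
        res = tf_lnc_correlation(tf, lnc)
        assert res["r"].loc["TF1", "L1"] == pytest.approx(1.0)

    def test_null_mask_rate(self):
        hits, total = 0, 0
        for seed in range(60):
            r = np.random.default_rng(seed)
            samples = [f"s{j}" for j in range(11)]
            tf = pd.DataFrame(r.standard_normal((4, 11)),
                              index=[f"T{i}" for i in range(4)], columns=samples)
            lnc = pd.DataFrame(r.standard_normal((4, 11)),
                               index=[f"L{i}" for i in range(4)], columns=samples)
            res = tf_lnc_correlation(tf, lnc)
            hits += res["n_significant"]
            total += res["n_pairs"]
        # joint criterion |r|>0.75 & p<0.01 at n=11 is conservative; the
        # attained rate must stay at or below the nominal 1%
        assert hits / total <= 0.01 + 0.01


def test_scan_regions_bh_scope(rng):
    pwms = [make_sharp_pwm("M0", "TF0", width=12, sharpness=0.99, seed=0)]
    regions = {}
    planted = set()
    for i in range(12):
        seq = "".join(rng.choice(list(BASES), 300))
        rid = f"r{i}"
        if i % 2 == 0:
            seq = seq[:100] + pwms[0].consensus() + seq[112:]
            planted.add(rid)
        regions[rid] = seq
    hits = scan_regions(pwms, regions, fdr=0.05)
    assert planted <= set(hits["region_id"])
    assert (hits["q"] >= hits["p"] - 1e-15).all()
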