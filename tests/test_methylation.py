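"""Bisulfite clone tabulation, region summaries, and the allele DMR test."""

from math import comb

import numpy as np
import pytest

from imprintscreen.genome import GenomicInterval
from imprintscreen.methylation import (
    METHYLATED,
    MISSING,
    UNMETHYLATED,
    BisulfiteAmplicon,
    allele_dmr_test,
    matrix_to_sequences,
    per_cpg_fraction,
    summarize_region,
    tabulate_clones,
)
from imprintscreen.simulate import TruthConfig, build_truth, simulate_bisulfite


def simple_amplicon(n_cpgs=4, with_snp=False):
    """Reference 'ACxx CG xx...' with evenly spaced CpGs and extra non-CpG Cs."""
    parts = ["AAC", "CAT"]  # two non-CpG Cs up front
    offsets = []
    pos = len("".join(parts))
    for _ in range(n_cpgs):
        parts.append("AT")
        pos += 2
        offsets.append(pos)
        parts.append("CG")
        pos += 2
        parts.append("CA")  # one non-CpG C after each CpG
        pos += 2
    ref = "".join(parts)
    snp_offset = 0 if with_snp else None
    return BisulfiteAmplicon(
        region=GenomicInterval("chr1", 0, len(ref)),
        reference=ref,
        cpg_offsets=tuple(offsets),
        snp_offset=snp_offset,
        snp_alleles=("A", "G") if with_snp else None,
    )


def clone_from(amplicon, methylated=(), convert=True, allele=None):
    chars = list(amplicon.reference)
    for i, off in enumerate(amplicon.cpg_offsets):
        chars[off] = "C" if i in methylated else "T"
    if convert:
        for off in amplicon.non_cpg_c_offsets:
            chars[off] = "T"
    if allele is not None:
        chars[amplicon.snp_offset] = allele
    return "".join(chars)


class TestTabulateClones:
    def test_fully_converted_clone_all_unmethylated(self):
        amp = simple_amplicon()
        m = tabulate_clones(amp, [clone_from(amp)])
        assert (m.calls[0] == UNMETHYLATED).all()
        assert m.conversion[0] == 1.0
        assert not m.excluded[0]

    def test_fully_methylated_clone(self):
        amp = simple_amplicon()
        m = tabulate_clones(amp, [clone_from(amp, methylated=range(4))])
        assert (m.calls[0] == METHYLATED).all()
        assert m.conversion[0] == 1.0

    def test_poor_conversion_flagged_excluded(self):
        amp = simple_amplicon(n_cpgs=4)  # 6 non-CpG Cs
        chars = list(clone_from(amp))
        # retain 3 of 6 non-CpG Cs -> conversion 0.5
        for off in amp.non_cpg_c_offsets[:3]:
            chars[off] = "C"
        m = tabulate_clones(amp, ["".join(chars)])
        assert m.conversion[0] == pytest.approx(0.5)
        assert m.excluded[0]

    def test_unexpected_base_is_missing(self):
        amp = simple_amplicon()
        chars = list(clone_from(amp))
        chars[amp.cpg_offsets[0]] = "G"
        m = tabulate_clones(amp, ["".join(chars)])
        assert m.calls[0, 0] == MISSING

    def test_length_mismatch_rejected(self):
        amp = simple_amplicon()
        with pytest.raises(ValueError, match="length"):
            tabulate_clones(amp, ["ACGT"])

    def test_no_cpg_amplicon_rejected(self):
        with pytest.raises(ValueError):
            BisulfiteAmplicon(
                region=GenomicInterval("chr1", 0, 4),
                reference="AAAA",
                cpg_offsets=(0,),
            )

    def test_allele_labels_from_phasing_snp(self):
        amp = simple_amplicon(with_snp=True)
        seqs = [clone_from(amp, allele="A"), clone_from(amp, allele="G")]
        m = tabulate_clones(amp, seqs)
        assert m.allele_labels == ["A", "G"]

    def test_round_trip_matrix_to_sequences(self):
        amp = simple_amplicon(with_snp=True)
        seqs = [
            clone_from(amp, methylated=(0, 2), allele="A"),
            clone_from(amp, methylated=(1, 3), allele="G"),
        ]
        m = tabulate_clones(amp, seqs)
        regenerated = matrix_to_sequences(amp, m)
        assert regenerated == seqs


class TestSummarizeRegion:
    def _matrix(self, rows):
        amp = simple_amplicon(n_cpgs=len(rows[0]))
        seqs = [
            clone_from(amp, methylated=[j for j, v in enumerate(r) if v])
            for r in rows
        ]
        return tabulate_clones(amp, seqs)

    def test_all_unmethylated_16x16_is_hypomethylated(self):
        m = self._matrix([[0] * 16 for _ in range(16)])
        s = summarize_region(m)
        assert s["mean_fraction"] == 0.0
        assert s["status"] == "hypomethylated"

    def test_all_methylated_is_hypermethylated(self):
        m = self._matrix([[1] * 8 for _ in range(8)])
        assert summarize_region(m)["status"] == "hypermethylated"

    def test_half_methylated_is_intermediate(self):
        rows = [[1] * 4 if i % 2 == 0 else [0] * 4 for i in range(8)]
        s = summarize_region(self._matrix(rows))
        assert s["mean_fraction"] == pytest.approx(0.5)
        assert s["status"] == "intermediate"

    def test_monotone_under_single_flip(self):
        rng = np.random.default_rng(4)
        rows = (rng.random((10, 6)) < 0.4).astype(int)
        m = self._matrix(rows.tolist())
        base = per_cpg_fraction(m)
        for _ in range(20):
            i, j = rng.integers(10), rng.integers(6)
            if m.calls[i, j] == UNMETHYLATED:
                m.calls[i, j] = METHYLATED
                flipped = per_cpg_fraction(m)
                assert (flipped >= base - 1e-12).all()
                base = flipped

    def test_all_excluded_rejected(self):
        amp = simple_amplicon()
        m = tabulate_clones(amp, [clone_from(amp, convert=False)])
        assert m.excluded.all()
        with pytest.raises(ValueError):
            summarize_region(m)


class TestAlleleDmrTest:
    def _split_matrix(self, n_per_allele=8, n_cpgs=18, p_a=1.0, p_b=0.0, rng=None):
        amp = simple_amplicon(n_cpgs=n_cpgs, with_snp=True)
        seqs = []
        for allele, p in (("A", p_a), ("G", p_b)):
            for _ in range(n_per_allele):
                if rng is None:
                    meth = range(n_cpgs) if p >= 1 else ()
                else:
                    meth = [j for j in range(n_cpgs) if rng.random() < p]
                seqs.append(clone_from(amp, methylated=meth, allele=allele))
        return tabulate_clones(amp, seqs)

    def test_no_snp_not_assessable(self):
        amp = simple_amplicon(with_snp=False)
        m = tabulate_clones(amp, [clone_from(amp)] * 10)
        assert allele_dmr_test(m)["verdict"] == "not_assessable"

    def test_too_few_clones_not_assessable(self):
        m = self._split_matrix(n_per_allele=3)
        assert allele_dmr_test(m)["verdict"] == "not_assessable"

    def test_fully_split_alleles_positive_with_enumerated_p(self):
        """8v8 clones fully split: per-CpG one-sided exact p = 1/C(16,8)."""
        m = self._split_matrix(n_per_allele=8, n_cpgs=18)
        res = allele_dmr_test(m)
        assert res["verdict"] == "dmr_positive"
        expected_p = 1 / comb(16, 8)
        assert np.allclose(res["p_values"], expected_p, rtol=1e-9)
        assert expected_p == pytest.approx(7.77e-5, rel=1e-2)

    def test_identical_methylation_negative(self):
        m = self._split_matrix(p_a=1.0, p_b=1.0)
        assert allele_dmr_test(m)["verdict"] == "dmr_negative"

    def test_power_and_false_positive_rate_over_seeded_replicates(self):
        """Planted 0.95 vs 0.05 split is detected in >=99% of 200 replicates;
        equal 0.05/0.05 methylation triggers in <=1%."""
        rng = np.random.default_rng(1000)
        positive = sum(
            allele_dmr_test(
                self._split_matrix(n_per_allele=16, n_cpgs=16, p_a=0.95, p_b=0.05,
                                   rng=rng)
            )["verdict"] == "dmr_positive"
            for _ in range(200)
        )
        assert positive >= 198
        null_positive = sum(
            allele_dmr_test(
                self._split_matrix(n_per_allele=16, n_cpgs=16, p_a=0.05, p_b=0.05,
                                   rng=rng)
            )["verdict"] == "dmr_positive"
            for _ in range(200)
        )
        assert null_positive <= 2


class TestCloneIO:
    def test_fasta_round_trip(self, tmp_path):
        from imprintscreen.methylation import read_clones_fasta, write_clones_fasta

        amp = simple_amplicon()
        seqs = [clone_from(amp, methylated=(0,)), clone_from(amp)]
        names = ["c1", "c2"]
        path = tmp_path / "clones.fasta"
        write_clones_fasta(path, names, seqs)
        back_names, back_seqs = read_clones_fasta(path)
        assert back_names == names and back_seqs == seqs

    def test_lollipop_plot_written(self, tmp_path):
        from imprintscreen.methylation import plot_lollipop

        amp = simple_amplicon()
        m = tabulate_clones(amp, [clone_from(amp, methylated=(0, 2))] * 3)
        out = tmp_path / "lollipop.png"
        plot_lollipop(m, out)
        assert out.stat().st_size > 0


class TestSimulatedBisulfite:
    def test_planted_extremes_and_binomial_band(self):
        cfg = TruthConfig(seed=5)
        truth = build_truth(cfg)
        gids = sorted(
            g for g, c in truth.gene_class.items() if c.startswith("imprinted")
        )[:1]
        for probs, check in [
            ((0.0, 0.0), lambda f: f == 0.0),
            ((1.0, 1.0), lambda f: f == 1.0),
            ((0.5, 0.5), lambda f: abs(f - 0.5) <= 0.1),
        ]:
            sim = simulate_bisulfite(truth, cfg, gene_ids=gids,
                                     methylation_probs=probs)
            amp, seqs, names = sim[gids[0]]
            m = tabulate_clones(amp, seqs, names)
            frac = float(np.nanmean(per_cpg_fraction(m)))
            assert check(frac), (probs, frac)
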