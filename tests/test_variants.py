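import pytest

from affopt.motifs import ETS, Site, matches
from affopt.pbm import revcomp
from affopt.variants import (
    ClassThresholds,
    RefMismatchError,
    Variant,
    VariantEffect,
    WindowEffect,
    apply_snv,
    classify_snv,
    classify_variant,
    default_thresholds,
    exclude_overlapping_site_snvs,
    variant_window_effects,
)

TH = ClassThresholds()  # ETS defaults: opt 1.59, neutral [0.8, 1.25]


class TestApplySnv:
    def test_substitution(self):
        assert apply_snv("ACGT", Variant("s", 1, "C", "G")) == "AGGT"

    def test_involution(self):
        seq = "ACGTACGT"
        v = Variant("s", 3, "T", "A")
        back = apply_snv(apply_snv(seq, v), Variant("s", 3, "A", "T"))
        assert back == seq

    def test_ref_mismatch_reports_bases(self):
        with pytest.raises(RefMismatchError, match="expected ref A.*has C"):
            apply_snv("ACGT", Variant("s", 1, "A", "G"))


def _oracle_windows(seq, v, pattern, table):
    """Brute-force enumeration of the (up to) 8 x 2 covering windows."""
    alt_seq = seq[: v.pos] + v.alt + seq[v.pos + 1:]
    out = []
    for start in range(max(0, v.pos - 7), min(v.pos, len(seq) - 8) + 1):
        for strand in "+-":
            rk, ak = seq[start:start + 8], alt_seq[start:start + 8]
            if strand == "-":
                rk, ak = revcomp(rk), revcomp(ak)
            rm, am = matches(rk, pattern), matches(ak, pattern)
            if rm and am:
                out.append((start, strand, table.affinity(ak) / table.affinity(rk)))
    return out


class TestWindowEffects:
    def test_poly_c_context_has_no_windows(self, pbm_table):
        eff = variant_window_effects("C" * 30, Variant("s", 15, "C", "A"),
                                     ETS, pbm_table)
        assert eff.windows == []

    def test_overlapping_windows_all_reported(self, pbm_table):
        # two overlapping GGAA frames share the varied base
        seq = "CC" + "GGAAGGAA" + "CCCC"
        v = Variant("s", 6, "G", "T")
        eff = variant_window_effects(seq, v, ETS, pbm_table)
        oracle = _oracle_windows(seq, v, ETS, pbm_table)
        dual = [(w.start, w.strand, w.fold) for w in eff.windows if w.match == "dual"]
        assert sorted(dual) == sorted(oracle)
        assert eff.best_fold == pytest.approx(max(f for _s, _t, f in oracle))

    def test_fold_against_oracle_for_every_snv(self, pbm_table, enhancer):
        seq, _ = enhancer
        for pos in range(0, len(seq), 17):  # systematic subsample
            for alt in "ACGT":
                if alt == seq[pos]:
                    continue
                v = Variant("enh", pos, seq[pos], alt)
                eff = variant_window_effects(seq, v, ETS, pbm_table)
                oracle = _oracle_windows(seq, v, ETS, pbm_table)
                folds = [w.fold for w in eff.windows if w.match == "dual"]
                assert sorted(folds) == sorted(f for _s, _t, f in oracle)


class TestClassify:
    def _effect_with_folds(self, folds, alt_only=False, ref_only=False):
        v = Variant("s", 0, "A", "C")
        windows = [
            WindowEffect(0, "+", "CCGGAACC", "CCGGAACC", 0.1, 0.1 * f, f, "dual")
            for f in folds
        ]
        if alt_only:
            windows.append(WindowEffect(1, "+", "CCCCCCCC", "CCGGAACC",
                                        None, 0.1, None, "alt_only"))
        if ref_only:
            windows.append(WindowEffect(1, "+", "CCGGAACC", "CCCCCCCC",
                                        0.1, None, None, "ref_only"))
        eff = VariantEffect(v, "ETS", windows)
        if folds:
            eff.best_fold = max(folds)
        return eff

    def test_threshold_is_inclusive(self):
        assert classify_snv(self._effect_with_folds([1.6]), TH).label \
            == "affinity_optimizing"
        assert classify_snv(self._effect_with_folds([1.59]), TH).label \
            == "affinity_optimizing"

    def test_neutral_band(self):
        assert classify_snv(self._effect_with_folds([1.0]), TH).label \
            == "affinity_neutral_in_site"
        assert classify_snv(self._effect_with_folds([0.8, 1.25]), TH).label \
            == "affinity_neutral_in_site"

    def test_decreasing(self):
        assert classify_snv(self._effect_with_folds([0.5]), TH).label \
            == "affinity_decreasing"

    def test_subthreshold_increase_is_not_optimizing(self):
        eff = classify_snv(self._effect_with_folds([1.4]), TH)
        assert eff.label == "affinity_increasing_subthreshold"
        assert eff.analysis_group == "all-other"

    def test_de_novo_and_ablating(self):
        assert classify_snv(self._effect_with_folds([], alt_only=True), TH).label \
            == "de_novo_site"
        assert classify_snv(self._effect_with_folds([], ref_only=True), TH).label \
            == "site_ablating"

    def test_optimizing_takes_precedence_over_alt_only(self):
        eff = self._effect_with_folds([1.7], alt_only=True)
        assert classify_snv(eff, TH).label == "affinity_optimizing"

    def test_empty_windows_not_in_site(self):
        eff = classify_snv(self._effect_with_folds([]), TH)
        assert eff.label == "not_in_site"
        assert eff.analysis_group == "all-other"

    def test_relaxed_threshold_for_sparse_datasets(self):
        # the >1.0 configuration used when few variants reach 1.59-fold
        th = ClassThresholds(opt_fold=1.26, neutral_band=(0.8, 1.25))
        assert classify_snv(self._effect_with_folds([1.3]), th).label \
            == "affinity_optimizing"

    def test_thresholds_validated(self):
        with pytest.raises(ValueError):
            ClassThresholds(opt_fold=1.2, neutral_band=(0.8, 1.25))

    def test_family_defaults(self):
        assert default_thresholds("ETS").opt_fold == 1.59
        assert default_thresholds("AP-1").opt_fold == 1.5
        assert default_thresholds("IRF").opt_fold == 1.5


class TestInvariants:
    def test_ref_alt_swap_inverts_folds(self, pbm_table, enhancer):
        seq, _ = enhancer
        for pos in range(0, len(seq), 23):
            for alt in "ACGT":
                if alt == seq[pos]:
                    continue
                v = Variant("enh", pos, seq[pos], alt)
                fwd = variant_window_effects(seq, v, ETS, pbm_table)
                alt_seq = apply_snv(seq, v)
                back = variant_window_effects(
                    alt_seq, Variant("enh", pos, alt, seq[pos]), ETS, pbm_table
                )
                f1 = sorted(w.fold for w in fwd.windows if w.match == "dual")
                f2 = sorted((1 / w.fold for w in back.windows if w.match == "dual"),
                            reverse=False)
                assert f1 == pytest.approx(sorted(f2))

    def test_strand_invariance_of_labels(self, pbm_table, enhancer):
        comp = str.maketrans("ACGT", "TGCA")
        seq, _ = enhancer
        rc = revcomp(seq)
        for pos in range(0, len(seq), 29):
            for alt in "ACGT":
                if alt == seq[pos]:
                    continue
                v = Variant("enh", pos, seq[pos], alt)
                mirrored = Variant("enh", len(seq) - 1 - pos,
                                   seq[pos].translate(comp), alt.translate(comp))
                a = classify_variant(seq, v, ETS, pbm_table, TH)
                b = classify_variant(rc, mirrored, ETS, pbm_table, TH)
                assert a.label == b.label
                if a.best_fold is not None:
                    assert a.best_fold == pytest.approx(b.best_fold)

    def test_motif_free_sequence_all_not_in_site(self, pbm_table):
        seq = "C" * 40
        labels = {
            classify_variant(seq, Variant("s", pos, "C", alt), ETS, pbm_table,
                             TH).label
            for pos in range(len(seq))
            for alt in "AGT"
        }
        assert labels <= {"not_in_site", "de_novo_site"}
        # poly-C specifically cannot gain a GGAW core by one substitution
        assert labels == {"not_in_site"}


class TestOverlapExclusion:
    def test_bookkeeping(self, pbm_table):
        sites = [
            Site("s", 0, "+", "CCGGAACC", 0.1),
            Site("s", 4, "+", "AACCGGAA", 0.1),  # overlaps the first on 4..8
            Site("s", 20, "+", "CCGGAACC", 0.1),
        ]
        effects = [
            classify_snv(VariantEffect(Variant("s", pos, "A", "C"), "ETS", []), TH)
            for pos in (5, 6, 2, 21, 35)
        ]
        survivors, excluded = exclude_overlapping_site_snvs(effects, sites)
        assert len(survivors) == 3
        assert sorted(e.variant.pos for e, _n in excluded) == [5, 6]
        assert all(n == 2 for _e, n in excluded)
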