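"""Terminus classification, target-decoy FDR, ratio and mass computation."""

import numpy as np
import pytest
from pyteomics import mass as pt_mass

from tailstriage import (
    LabelScheme,
    NTermPeptide,
    ProteinRecord,
    classify_terminus,
    fdr_filter,
    peptide_monoisotopic_mass,
    quantify_ratio,
    rollup_psms,
)


def brute_force_fdr(psms, q):
    """Oracle: try every observed score as threshold, smallest valid wins."""
    targets = [p for p in psms if not p.is_decoy]
    decoys = [p for p in psms if p.is_decoy]
    best = None
    for t in sorted({p.psm_score for p in psms}):
        n_t = sum(1 for p in targets if p.psm_score >= t)
        n_d = sum(1 for p in decoys if p.psm_score >= t)
        if n_t > 0 and n_d / n_t <= q:
            best = t
            break
    if best is None:
        return [], None
    return [p for p in targets if p.psm_score >= best], best


def pep(score, decoy=False, seq="AAAA", acc="P1", start=5, light=100.0, heavy=100.0,
        rep="r1", mod="dimethyl_light"):
    return NTermPeptide(
        sequence=seq, accession=acc, start=start, nterm_mod=mod,
        intensity_light=light, intensity_heavy=heavy, psm_score=score,
        is_decoy=decoy, replicate_id=rep,
    )


PROT = ProteinRecord(accession="P1", gene_symbol="G", species="rabbit",
                     sequence="MAAAVLSTTT" * 20)


class TestClassifyTerminus:
    def test_start_one_is_native(self):
        assert classify_terminus(pep(50, start=1), PROT) == "native"

    def test_start_two_dimethyl_is_native(self):
        """Initiator-Met removal: position 2 still counts as the own terminus."""
        assert classify_terminus(pep(50, start=2), PROT) == "native"

    @pytest.mark.parametrize("mod", ["dimethyl_light", "dimethyl_heavy", "pyroglu", "free"])
    def test_deep_start_with_in_vitro_label_is_neo(self, mod):
        assert classify_terminus(pep(50, start=127, mod=mod), PROT) == "neo"

    def test_deep_acetyl_start_is_native(self):
        assert classify_terminus(pep(50, start=10, mod="acetyl"), PROT) == "native"

    def test_never_neo_at_shallow_starts(self):
        for start in (1, 2):
            for mod in ("dimethyl_light", "acetyl", "free", "pyroglu"):
                assert classify_terminus(pep(50, start=start, mod=mod), PROT) != "neo"

    def test_unmappable_peptide_rejected(self):
        with pytest.raises(ValueError, match="does not map"):
            classify_terminus(pep(50, start=500), PROT)


class TestFdrFilter:
    def test_no_decoys_everything_passes(self):
        psms = [pep(s) for s in range(1, 11)]
        passing, thr = fdr_filter(psms, 0.05)
        assert len(passing) == 10

    def test_known_threshold_instance(self):
        """10 targets 10..1, decoys at 8.5 and 0.5: oracle fixes the cut."""
        psms = [pep(float(s)) for s in range(10, 0, -1)]
        psms += [pep(8.5, decoy=True), pep(0.5, decoy=True)]
        passing, thr = fdr_filter(psms, 0.10)
        oracle_passing, oracle_thr = brute_force_fdr(psms, 0.10)
        assert thr == oracle_thr
        assert sorted(p.psm_score for p in passing) == sorted(
            p.psm_score for p in oracle_passing
        )
        # with both decoys counted at low thresholds 2/10 > 0.1, so the cut
        # must clear the 0.5 decoy
        assert thr > 0.5

    def test_matches_brute_force_on_random_instances(self):
        """Streaming implementation == exhaustive threshold search, 100 draws."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            n_t = int(rng.integers(5, 60))
            n_d = int(rng.integers(0, 30))
            q = float(rng.uniform(0.01, 0.3))
            psms = [pep(float(s)) for s in rng.normal(10, 4, size=n_t)]
            psms += [pep(float(s), decoy=True) for s in rng.normal(6, 4, size=n_d)]
            got, thr = fdr_filter(psms, q)
            want, want_thr = brute_force_fdr(psms, q)
            assert thr == want_thr
            assert sorted(p.psm_score for p in got) == sorted(p.psm_score for p in want)

    def test_order_invariance(self):
        rng = np.random.default_rng(7)
        psms = [pep(float(s)) for s in rng.normal(10, 4, size=30)]
        psms += [pep(float(s), decoy=True) for s in rng.normal(6, 4, size=10)]
        a, _ = fdr_filter(psms, 0.1)
        b, _ = fdr_filter(psms[::-1], 0.1)
        assert sorted(p.psm_score for p in a) == sorted(p.psm_score for p in b)

    def test_decoys_never_returned(self):
        psms = [pep(10.0), pep(9.0, decoy=True)]
        passing, _ = fdr_filter(psms, 0.5)
        assert all(not p.is_decoy for p in passing)

    def test_impossible_q_warns_and_empties(self):
        psms = [pep(5.0), pep(10.0, decoy=True), pep(11.0, decoy=True)]
        with pytest.warns(UserWarning):
            passing, thr = fdr_filter(psms, 0.05)
        assert passing == [] and thr is None

    def test_invalid_q_rejected(self):
        with pytest.raises(ValueError):
            fdr_filter([pep(5.0)], 1.5)

    def test_plus_one_correction_is_more_conservative(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            psms = [pep(float(s)) for s in rng.normal(10, 4, size=40)]
            psms += [pep(float(s), decoy=True) for s in rng.normal(6, 4, size=12)]
            plain, _ = fdr_filter(psms, 0.1)
            import warnings as _w
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                corrected, _ = fdr_filter(psms, 0.1, plus_one=True)
            assert {p.psm_score for p in corrected} <= {p.psm_score for p in plain}


class TestQuantifyRatio:
    scheme = LabelScheme(orientation={"r1": "light_control", "r2": "heavy_control"})

    def test_light_control_twofold(self):
        q = quantify_ratio(pep(50, light=200, heavy=100), self.scheme)
        assert q.log2_ratio == pytest.approx(1.0)

    def test_heavy_control_twofold(self):
        q = quantify_ratio(pep(50, light=100, heavy=200, rep="r2"), self.scheme)
        assert q.log2_ratio == pytest.approx(1.0)

    def test_1_5_fold_clears_paper_threshold(self):
        q = quantify_ratio(pep(50, light=150, heavy=100), self.scheme)
        assert q.log2_ratio == pytest.approx(0.585, abs=1e-3)
        assert q.log2_ratio > 0.58

    def test_swap_invariance_property(self):
        """Swapping channels together with the orientation flag is a no-op."""
        rng = np.random.default_rng(5)
        for _ in range(50):
            light, heavy = rng.lognormal(13, 1, size=2)
            a = quantify_ratio(pep(50, light=light, heavy=heavy, rep="r1"), self.scheme)
            b = quantify_ratio(pep(50, light=heavy, heavy=light, rep="r2"), self.scheme)
            assert a.log2_ratio == pytest.approx(b.log2_ratio, rel=1e-12)

    def test_both_channels_missing_rejected(self):
        with pytest.raises(ValueError, match="unquantifiable"):
            quantify_ratio(pep(50, light=None, heavy=None), self.scheme)

    def test_one_channel_missing_excluded_by_default(self):
        assert quantify_ratio(pep(50, light=None, heavy=100), self.scheme) is None

    def test_one_channel_missing_capped_mode(self):
        q = quantify_ratio(
            pep(50, light=None, heavy=100), self.scheme, missing_policy="cap"
        )
        assert q.log2_ratio == -6.0  # control (light) missing -> fully depleted
        q = quantify_ratio(
            pep(50, light=100, heavy=0), self.scheme, missing_policy="cap"
        )
        assert q.log2_ratio == 6.0  # zero intensity treated as missing

    def test_unknown_replicate_orientation_rejected(self):
        with pytest.raises(KeyError):
            quantify_ratio(pep(50, rep="rX"), self.scheme)


class TestRollup:
    def test_best_psm_represents_peptide_and_intensities_sum(self):
        psms = [
            pep(10, light=100, heavy=50),
            pep(20, light=30, heavy=None),
            pep(15, seq="CCCC", light=1, heavy=1),
        ]
        rolled = rollup_psms(psms)
        assert len(rolled) == 2
        main = next(p for p in rolled if p.sequence == "AAAA")
        assert main.psm_score == 20
        assert main.intensity_light == 130
        assert main.intensity_heavy == 50


class TestMass:
    def test_glycine_free_and_dimethylated(self):
        assert peptide_monoisotopic_mass("G") == pytest.approx(75.0320, abs=1e-3)
        assert peptide_monoisotopic_mass("G", "dimethyl_light") == pytest.approx(
            103.0623, abs=1e-3
        )

    def test_heavy_minus_light_is_label_increment(self):
        for seq in ("GASP", "KAKA", "WMV"):
            d = peptide_monoisotopic_mass(seq, "dimethyl_heavy") - \
                peptide_monoisotopic_mass(seq, "dimethyl_light")
            assert d == pytest.approx(6.0312, abs=1e-4)

    def test_lysine_label_adds_per_lysine_delta(self):
        base = peptide_monoisotopic_mass("KAK", "dimethyl_light")
        light = peptide_monoisotopic_mass("KAK", "dimethyl_light", lysine_label="light")
        heavy = peptide_monoisotopic_mass("KAK", "dimethyl_light", lysine_label="heavy")
        assert light - base == pytest.approx(2 * 28.0303, abs=1e-4)
        assert heavy - light == pytest.approx(2 * 6.0312, abs=1e-4)

    def test_matches_pyteomics_for_unmodified_peptides(self):
        for seq in ("PEPTIDE", "ACDEFGHIK", "WWW"):
            assert peptide_monoisotopic_mass(seq) == pytest.approx(
                pt_mass.calculate_mass(sequence=seq), abs=1e-3
            )

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            peptide_monoisotopic_mass("")

    def test_unknown_residue_rejected(self):
        with pytest.raises(ValueError):
            peptide_monoisotopic_mass("AXZ")


def test_label_scheme_invariant_enforced():
    with pytest.raises(ValueError):
        LabelScheme(delta_light=28.0, delta_heavy=35.0)
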