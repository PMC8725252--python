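"""Duplex alignment, energy model and target-pair prediction."""

import numpy as np
import pytest

from cernet.errors import ValidationError
from cernet.targets import (
    INITIATION_DG,
    STACK_TABLE,
    DuplexSite,
    ScoringScheme,
    align_duplex,
    duplex_energy,
    pairing_line,
    perfect_duplex_energy,
    predict_targets,
    rescore_alignment,
    reverse_complement,
)

from oracles import best_local_score_oracle


def _random_rna(rng, n):
    return "".join(rng.choice(list("ACGU"), size=n))


class TestAlignDuplex:
    def test_planted_perfect_complement_found_at_coordinates(self, rng):
        """A perfect reverse complement embedded at a known position is the
        top site, at exactly the planted coordinates, and its stored score
        survives independent re-scoring."""
        mirna = _random_rna(rng, 22)
        flank5 = _random_rna(rng, 100)
        flank3 = _random_rna(rng, 100)
        target = flank5 + reverse_complement(mirna) + flank3
        sites = align_duplex(mirna, target, min_report_score=100)
        top = sites[0]
        assert (top.target_start, top.target_end) == (101, 122)
        assert top.score == rescore_alignment(top)
        # full-length perfect duplex: every column scores `match`,
        # seed columns scaled -- verified against the column-walk re-scorer
        scheme = ScoringScheme()
        n_seed = scheme.seed_end - scheme.seed_start + 1
        assert top.score == scheme.match * (22 - n_seed) + scheme.match * scheme.seed_weight * n_seed

    def test_no_complement_means_no_passing_site(self):
        """A target that cannot pair (A vs A) yields nothing near the floor."""
        sites = align_duplex("A" * 22, "A" * 200)
        assert sites == []

    def test_empty_target_gives_empty_list(self):
        assert align_duplex("ACGUACGUACGUACGUACGUAC", "") == []

    def test_non_rna_character_rejected(self):
        with pytest.raises(ValidationError, match="non-RNA"):
            align_duplex("ACGUACGUACGXACGUACGUAC", "ACGU")

    def test_dna_input_transcribed_with_warning(self):
        with pytest.warns(UserWarning, match="transcribing"):
            sites = align_duplex("ACGTACGTACGTACGTACGTAC", "ACGT")
        assert all("T" not in s.aligned_mirna for s in sites)

    def test_exhaustive_oracle_equivalence_small_inputs(self, rng):
        """Top alignment score equals exhaustive enumeration over all local
        alignments for miRNA <= 10 nt and target <= 30 nt."""
        scheme = ScoringScheme()
        for _ in range(30):
            mirna = _random_rna(rng, int(rng.integers(4, 11)))
            target = _random_rna(rng, int(rng.integers(5, 31)))
            expected = best_local_score_oracle(mirna, target, scheme)
            sites = align_duplex(mirna, target, scheme)
            got = sites[0].score if sites else 0.0
            assert got == pytest.approx(expected), (mirna, target)

    def test_sites_non_overlapping_and_score_sorted(self, rng):
        mirna = _random_rna(rng, 22)
        rc = reverse_complement(mirna)
        target = _random_rna(rng, 50) + rc + _random_rna(rng, 50) + rc + _random_rna(rng, 50)
        sites = align_duplex(mirna, target, min_report_score=150)
        assert len(sites) >= 2
        assert sites[0].score >= sites[1].score
        spans = [(s.target_start, s.target_end) for s in sites]
        for i, (s1, e1) in enumerate(spans):
            for s2, e2 in spans[i + 1:]:
                assert e1 < s2 or e2 < s1

    def test_reversed_target_moves_the_site(self, rng):
        """Orientation matters: the reversed target does not reproduce the
        same site coordinates for a non-palindromic planted site."""
        mirna = _random_rna(rng, 22)
        target = _random_rna(rng, 40) + reverse_complement(mirna) + _random_rna(rng, 140)
        fwd = align_duplex(mirna, target, min_report_score=160)
        rev = align_duplex(mirna, target[::-1], min_report_score=160)
        assert fwd and (not rev or
                        (fwd[0].target_start, fwd[0].target_end)
                        != (rev[0].target_start, rev[0].target_end))

    def test_rescore_reproduces_score_on_gapped_alignments(self, rng):
        """Invariant: stored score equals a column-walk re-score, including
        alignments that contain gaps and mismatches."""
        checked = 0
        for _ in range(20):
            mirna = _random_rna(rng, 22)
            target = _random_rna(rng, 300)
            for site in align_duplex(mirna, target, min_report_score=20)[:5]:
                assert rescore_alignment(site) == pytest.approx(site.score)
                checked += 1
        assert checked > 10


class TestDuplexEnergy:
    def _site(self, mirna_aln, target_aln):
        return DuplexSite("m", "t", "mRNA", 1, len(target_aln.replace("-", "")),
                          1, len(mirna_aln.replace("-", "")),
                          mirna_aln, pairing_line(mirna_aln, target_aln), target_aln, 0.0, 0.0)

    def test_no_stacked_pairs_costs_only_initiation(self):
        """A single isolated pair has no stack: energy is the initiation penalty."""
        site = self._site("A", "U")
        assert duplex_energy(site) == pytest.approx(INITIATION_DG)
        assert duplex_energy(site) > -30.0

    def test_hand_summed_stack_for_fixed_duplex(self):
        """GCGC / CGCG duplex: three GC-family stacks summed from the table."""
        site = self._site("GCGC", "CGCG")
        expected = INITIATION_DG + STACK_TABLE["CG/GC"] + STACK_TABLE["GC/CG"] + STACK_TABLE["CG/GC"]
        assert duplex_energy(site) == pytest.approx(expected)

    def test_gap_breaks_the_stack(self):
        contiguous = self._site("GGGG", "CCCC")
        gapped = self._site("GG-GG", "CCACC")
        assert duplex_energy(gapped) > duplex_energy(contiguous)

    def test_perfect_22mer_clears_threshold(self, rng):
        """Perfect-duplex energy of simulated miRNAs sits below -30 kcal/mol."""
        for _ in range(10):
            mirna = _random_rna(rng, 22)
            gc = (mirna.count("G") + mirna.count("C")) / 22
            if gc >= 0.45:  # typical miRNA composition
                assert perfect_duplex_energy(mirna) <= -30.0


class TestPredictTargets:
    def test_all_planted_pairs_recovered_at_their_sites(self, sim):
        """Every simulated (miRNA, target) pair is reported and its best site
        overlaps the planted coordinates."""
        pairs = predict_targets(sim["mirnas"], sim["targets"], ScoringScheme())
        got = {(p.mirna_id, p.target_id): p for p in pairs}
        planted_by_pair = {}
        for s in sim["truth"].sites:
            planted_by_pair.setdefault((s.mirna_id, s.target_id), []).append(s)
        for key, sites in planted_by_pair.items():
            assert key in got, f"planted pair {key} not recovered"
            best = got[key].best_site
            assert any(best.target_start <= s.end and s.start <= best.target_end
                       for s in sites)

    def test_decoy_acceptance_is_rare(self, sim):
        pairs = predict_targets(sim["mirnas"], sim["targets"], ScoringScheme())
        n_mirnas = len(sim["mirnas"])
        n_decoys = sum(1 for t in sim["targets"] if t.startswith("DECOY"))
        false_hits = sum(1 for p in pairs if p.target_id.startswith("DECOY"))
        assert false_hits / (n_mirnas * n_decoys) < 0.05

    def test_empty_mirna_set_gives_empty_result(self, sim):
        assert predict_targets({}, sim["targets"], ScoringScheme()) == []

    def test_duplicate_fasta_id_rejected(self, tmp_path):
        fa = tmp_path / "m.fasta"
        fa.write_text(">a\nACGUACGUACGUACGUACGUAC\n>a\nACGUACGUACGUACGUACGUAC\n")
        with pytest.raises(ValidationError, match="duplicate"):
            predict_targets(fa, {}, ScoringScheme())

    def test_threshold_tightening_gives_subset(self, sim):
        """Raising score_min or lowering energy_max can only remove pairs."""
        mirnas = dict(list(sim["mirnas"].items())[:10])
        targets = dict(list(sim["targets"].items())[:30])
        base = {(p.mirna_id, p.target_id)
                for p in predict_targets(mirnas, targets, ScoringScheme())}
        stricter_score = {(p.mirna_id, p.target_id)
                          for p in predict_targets(mirnas, targets, ScoringScheme(score_min=200.0))}
        stricter_energy = {(p.mirna_id, p.target_id)
                           for p in predict_targets(mirnas, targets,
                                                    ScoringScheme(energy_max_kcal=-40.0))}
        assert stricter_score <= base
        assert stricter_energy <= base

    def test_best_site_has_maximal_score(self, sim):
        pairs = predict_targets(sim["mirnas"], dict(list(sim["targets"].items())[:40]),
                                ScoringScheme())
        for p in pairs[:20]:
            sites = align_duplex(sim["mirnas"][p.mirna_id], sim["targets"][p.target_id],
                                 min_report_score=160.0)
            passing = [s for s in sites if s.score > 160.0 and s.energy <= -30.0]
            assert p.best_site.score == max(s.score for s in passing)
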