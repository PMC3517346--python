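import numpy as np
import pytest

from paofam._dp import affine_align
from paofam.scoring import encode
from paofam.msa_conservation import (ActiveSitePanel, AlignmentProfile,
                                     column_conservation, conserved_columns,
                                     consensus_of,
                                     map_active_sites, progressive_align,
                                     read_alignment, write_alignment)


def direct_pairwise_global(a, b, scoring):
    ea, eb = encode(a), encode(b)
    cell = scoring.matrix[ea[:, None], eb[None, :]].astype(float)
    _, path = affine_align(cell, scoring.gap_open, scoring.gap_extend,
                           local=False)
    ra = "".join("-" if i is None else a[i] for i, _ in path)
    rb = "".join("-" if j is None else b[j] for _, j in path)
    return ra, rb


class TestProgressiveAlign:
    def test_identical_sequences_align_without_gaps(self, blosum62):
        seq = "MKVLAWHEAGHEEKLV"
        prof = progressive_align({f"s{k}": seq for k in range(5)}, blosum62)
        assert all(r == seq for r in prof.rows.values())
        assert np.all(column_conservation(prof) == 1.0)

    def test_two_sequences_equal_direct_global(self, blosum62):
        a, b = "MKVLAWHEAGHEEKLV", "MKVLAWHEGHEEKLVPP"
        prof = progressive_align({"a": a, "b": b}, blosum62)
        ra, rb = direct_pairwise_global(a, b, blosum62)
        assert prof.rows == {"a": ra, "b": rb}

    def test_row_order_equals_input_order(self, blosum62, dup_family):
        seqs = dup_family["sequences"]
        prof = progressive_align(seqs, blosum62)
        assert prof.ids == tuple(seqs)

    def test_single_sequence_warns(self, blosum62):
        with pytest.warns(UserWarning):
            prof = progressive_align({"x": "ACDEF"}, blosum62)
        assert prof.rows == {"x": "ACDEF"}

    def test_column_purity_against_truth_alignment(self, blosum62,
                                                   dup_family):
        """With indels recorded by the simulator, homologous residues
        should land in the same estimated columns (purity >= 0.95)."""
        seqs = dup_family["sequences"]
        truth_aln = dup_family["truth"].alignment
        prof = progressive_align(seqs, blosum62)
        # true column id per (row, residue index)
        true_cols = {}
        for sid, row in truth_aln.items():
            pos = 0
            for col, ch in enumerate(row):
                if ch != "-":
                    true_cols[(sid, pos)] = col
                    pos += 1
        pure = total = 0
        for col in range(prof.n_columns):
            members = []
            for sid, row in prof.rows.items():
                if row[col] != "-":
                    pos = sum(1 for c in row[:col] if c != "-")
                    members.append(true_cols[(sid, pos)])
            if len(members) < 2:
                continue
            counts = {c: members.count(c) for c in set(members)}
            pure += max(counts.values())
            total += len(members)
        assert pure / total >= 0.95


class TestConservation:
    def test_unanimous_column_scores_one(self):
        prof = {f"s{k}": "W" for k in range(10)}
        assert column_conservation(prof)[0] == 1.0
        assert conserved_columns(prof) == [0]

    def test_gap_counts_as_mismatch_and_threshold_inclusive(self):
        rows = {f"s{k}": "W" for k in range(9)}
        rows["s9"] = "-"
        scores = column_conservation(rows)
        assert scores[0] == pytest.approx(0.90)
        assert conserved_columns(rows, 0.90) == [0]          # >= 0.90
        assert conserved_columns(rows, 0.90, strict=True) == []

    def test_eighty_percent_not_flagged(self):
        rows = {f"s{k}": ("W" if k < 8 else "F") for k in range(10)}
        assert column_conservation(rows)[0] == pytest.approx(0.80)
        assert conserved_columns(rows, 0.90) == []

    def test_gapless_denominator_option(self):
        rows = {"a": "W", "b": "W", "c": "-", "d": "-"}
        assert column_conservation(rows)[0] == pytest.approx(0.5)
        assert column_conservation(
            rows, gaps_in_denominator=False)[0] == pytest.approx(1.0)

    def test_row_permutation_invariance(self, dup_family):
        aln = dup_family["truth"].alignment
        base = column_conservation(aln)
        shuffled = {k: aln[k] for k in sorted(aln, reverse=True)}
        assert np.allclose(base, column_conservation(shuffled))


class TestConsensus:
    def test_single_member_is_ungapped_row(self):
        prof = AlignmentProfile({"a": "AC-DE", "b": "ACWDE"})
        assert consensus_of(prof, ["a"]) == "ACDE"

    def test_alphabetic_tie_break(self):
        rows = {f"s{k}": ("E" if k < 5 else "D") for k in range(10)}
        prof = AlignmentProfile(rows)
        assert consensus_of(prof) == "D"

    def test_gap_majority_column_dropped(self):
        prof = AlignmentProfile({"a": "A-C", "b": "A-C", "c": "AWC"})
        assert consensus_of(prof) == "AC"

    def test_identical_rows_consensus_equals_row(self):
        prof = AlignmentProfile({"a": "MKWME", "b": "MKWME"})
        assert consensus_of(prof) == "MKWME"


class TestActiveSites:
    def test_reference_map_skips_gaps(self):
        prof = AlignmentProfile({"r": "A-CD", "x": "AWCD"})
        assert prof.reference_map("r") == {0: 1, 2: 2, 3: 3}

    def test_reference_only_subset_fully_conserved(self):
        prof = AlignmentProfile({"r": "AWCDE", "x": "AWQQQ"})
        panel = ActiveSitePanel("r", ((3, "C"), (5, "E")))
        reports = map_active_sites(prof, panel, subset_ids=["r"])
        assert all(r.conserved for r in reports)

    def test_mismatched_panel_raises(self):
        prof = AlignmentProfile({"r": "AWCDE"})
        panel = ActiveSitePanel("r", ((2, "Y"),))
        with pytest.raises(ValueError, match="panel/reference disagreement"):
            map_active_sites(prof, panel)

    def test_positions_must_increase(self):
        with pytest.raises(ValueError):
            ActiveSitePanel("r", ((5, "A"), (3, "C")))

    def test_subfamily_specific_pocket_contrast(self, dup_family):
        """Columns constrained only in one paralog lineage report as
        conserved within that subfamily and free in the other (the
        SMO-specific polar-pocket analog)."""
        from paofam.synthetic_data import (DuplicationScenario,
                                           default_params,
                                           random_species_tree,
                                           simulate_family)
        # deep divergence so an unconstrained column cannot stay conserved
        # within a subfamily by chance
        species = random_species_tree(10, seed=77, min_branch=0.25,
                                      max_branch=0.45)
        clade = next(species.clade_leafset(nd)
                     for nd in species.tree.preorder_internal_node_iter()
                     if 4 <= len(species.clade_leafset(nd)) <= 6)
        scen = DuplicationScenario(
            duplication_clade=clade,
            locus_constrained={"A": frozenset({50, 60})})
        params = default_params(p_invariant=0.0, gamma_shape=None,
                                indel_rate=0.0, seed=13)
        seqs, truth = simulate_family(species, scen, params,
                                      root_length=120)
        prof = AlignmentProfile(truth.alignment)
        a_ids = sorted(truth.records[truth.records.locus == "A"].sequence_id)
        b_ids = sorted(truth.records[truth.records.locus == "B"].sequence_id)
        ref = a_ids[0]
        refmap = truth.root_column_positions
        panel_positions = []
        for root_col in (50, 60):
            col = refmap[root_col]
            pos = sum(1 for c in range(col)
                      if truth.alignment[ref][c] != "-") + 1
            panel_positions.append((pos, truth.alignment[ref][col]))
        panel = ActiveSitePanel(ref, tuple(sorted(panel_positions)))
        in_a = map_active_sites(prof, panel, subset_ids=a_ids)
        in_b = map_active_sites(prof, panel, subset_ids=b_ids)
        assert all(r.conserved for r in in_a)
        assert not all(r.conserved for r in in_b)


class TestIO:
    def test_fasta_round_trip(self, tmp_path, dup_family):
        prof = AlignmentProfile(dup_family["truth"].alignment)
        path = tmp_path / "aln.fasta"
        write_alignment(prof, path)
        assert read_alignment(path).rows == prof.rows

    def test_clustal_import(self, tmp_path):
        text = ("CLUSTAL W (1.82) multiple sequence alignment\n\n"
                "s1   MKV-AW\n"
                "s2   MKVLAW\n")
        path = tmp_path / "aln.aln"
        path.write_text(text)
        prof = read_alignment(path, fmt="clustal")
        assert prof.rows == {"s1": "MKV-AW", "s2": "MKVLAW"}
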