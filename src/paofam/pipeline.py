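"""Dependency-ordered pipeline driver.

Runs the stages

    simulate|ingest -> search -> chain -> families -> align -> conserve
    -> tree -> reconcile -> isoforms -> report

over a simulated (or user-supplied) protein family, writing one output
file set per stage plus a run manifest that records the configuration,
seeds and per-stage row counts.  Re-running with an identical
configuration reproduces identical outputs.

Threshold defaults are the study's: E-value cutoff 1e-10, identity >= 30%,
bitscore >= 50, coverage >= 50% of both sequences, conservation threshold
90%, 500 bootstrap replicates.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

from . import __version__
from .family_builder import (FilterThresholds, apply_filters,
                             reciprocal_edges,
                             single_linkage_families, write_edges,
                             write_families)
from .hit_chaining import chain_all, write_chain_table
from .isoform_analysis import parsimony_gain
from .msa_conservation import (AlignmentProfile, consensus_of,
                               progressive_align, read_alignment,
                               write_alignment, write_conservation_table)
from .pairwise_search import (all_vs_all, read_fasta, write_fasta,
                              write_hit_table)
from .phylogeny import (as_newick, bootstrap_support, root_with_outgroup,
                        write_newick)
from .reconciliation import (reconcile, reconciliation_summary,
                             subfamily_monophyly)
from .scoring import ScoringScheme
from .synthetic_data import (DuplicationScenario, SpeciesTree,
                             default_params, random_species_tree,
                             simulate_family)

log = logging.getLogger("paofam")

STAGES = ("simulate", "search", "chain", "families", "align", "conserve",
          "tree", "reconcile", "isoforms", "report")


@dataclass
class RunConfig:
    """Pipeline configuration; defaults are the study's stated values."""

    outdir: str = "paofam_run"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    # inputs: either a FASTA to ingest, or the built-in demo simulation
    input_fasta: str | None = None
    species_newick: str | None = None
    outgroup: str | None = None
    # simulation knobs
    n_taxa: int = 12
    root_length: int = 300
    p_invariant: float = 0.1
    gamma_shape: float = 1.0
    indel_rate: float = 0.002
    n_constrained: int = 12
    # thresholds (study defaults)
    evalue_cutoff: float = 1e-10
    min_identity: float = 0.30
    min_bitscore: float = 50.0
    min_coverage_both: float = 0.50
    conservation_threshold: float = 0.90
    bootstrap_replicates: int = 500
    distance_correction: str = "poisson"

    def thresholds(self) -> FilterThresholds:
        return FilterThresholds(self.min_identity, self.min_bitscore,
                                self.min_coverage_both, True)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        payload = json.loads(Path(path).read_text())
        payload.pop("version", None)
        payload["stages"] = tuple(payload.get("stages", STAGES))
        return cls(**payload)

    def to_json(self, path: str | Path) -> None:
        payload = {"version": __version__, **asdict(self)}
        payload["stages"] = list(self.stages)
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def demo_scenario(species: SpeciesTree) -> DuplicationScenario:
    """The standard demo scenario: duplication on the stem of the larger
    child clade of the root (minus the outgroup side), long-isoform block
    restricted to a subclade of the duplicated clade."""
    root_kids = species.tree.seed_node.child_nodes()
    clades = sorted((species.clade_leafset(c) for c in root_kids), key=len)
    dup_clade = clades[-1]
    if species.outgroup_taxon in dup_clade and len(clades) > 1:
        dup_clade = clades[0]
    # isoform clade: a proper subclade of the duplication clade when one
    # exists, else the duplication clade itself
    iso = dup_clade
    for node in species.tree.preorder_node_iter():
        ls = species.clade_leafset(node)
        if ls < dup_clade and 2 <= len(ls) < len(dup_clade):
            iso = ls
            break
    return DuplicationScenario(duplication_clade=dup_clade,
                               isoform_clade=iso)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the run directory."""
    unknown = [s for s in config.stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")
    if config.input_fasta and not Path(config.input_fasta).exists():
        raise FileNotFoundError(config.input_fasta)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_json(outdir / "config.json")
    scoring = ScoringScheme.blosum62()
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "stages": {}, "thresholds": asdict(config.thresholds())}
    state: dict = {}

    def done(stage: str, **counts) -> None:
        manifest["stages"][stage] = {"status": "ok", **counts}
        log.info("stage %s: %s", stage, counts)

    def skipped(stage: str) -> None:
        manifest["stages"][stage] = {"status": "skipped"}

    try:
        _run_stages(config, scoring, outdir, state, done, skipped)
    except Exception as exc:
        stage = state.get("_current", "?")
        manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True))
        raise
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    return outdir


def _run_stages(config, scoring, outdir, state, done, skipped):
    # -- simulate / ingest ------------------------------------------------
    state["_current"] = "simulate"
    if "simulate" in config.stages:
        if config.input_fasta:
            seqs = read_fasta(config.input_fasta)
            state["sequences"] = seqs
            if config.species_newick:
                state["species"] = SpeciesTree.from_newick(
                    config.species_newick,
                    config.outgroup or sorted(seqs)[0])
            done("simulate", n_sequences=len(seqs), source="ingest")
        else:
            species = (SpeciesTree.from_newick(config.species_newick,
                                               config.outgroup)
                       if config.species_newick and config.outgroup
                       else random_species_tree(config.n_taxa, config.seed))
            scenario = demo_scenario(species)
            params = default_params(
                p_invariant=config.p_invariant,
                gamma_shape=config.gamma_shape,
                indel_rate=config.indel_rate,
                constrained_columns=frozenset(
                    range(0, config.n_constrained * 10, 10)),
                seed=config.seed)
            seqs, truth = simulate_family(species, scenario, params,
                                          root_length=config.root_length)
            state.update(sequences=seqs, truth=truth, species=species,
                         scenario=scenario)
            write_fasta(seqs, outdir / "family.fasta")
            truth.write_tsv(outdir / "truth.tsv")
            (outdir / "true_tree.nwk").write_text(truth.true_tree)
            (outdir / "species_tree.nwk").write_text(
                as_newick(species.tree))
            done("simulate", n_sequences=len(seqs),
                 n_taxa=len(species.taxa()))
    else:
        skipped("simulate")
        fasta = outdir / "family.fasta"
        if fasta.exists():
            state["sequences"] = read_fasta(fasta)

    # -- search -----------------------------------------------------------
    state["_current"] = "search"
    if "search" in config.stages:
        if "sequences" not in state:
            raise FileNotFoundError("missing inputs: no sequences to search")
        hits = all_vs_all(state["sequences"], scoring,
                          evalue_cutoff=config.evalue_cutoff)
        state["hits"] = hits
        write_hit_table(hits, outdir / "hits.tsv")
        done("search", n_hits=len(hits))
    else:
        skipped("search")

    # -- chain ------------------------------------------------------------
    state["_current"] = "chain"
    if "chain" in config.stages and "hits" in state:
        chains = chain_all(state["hits"])
        state["chains"] = chains
        write_chain_table(chains, outdir / "chains.tsv")
        done("chain", n_pairs=len(chains))
    else:
        skipped("chain")

    # -- families ---------------------------------------------------------
    state["_current"] = "families"
    if "families" in config.stages and "chains" in state:
        lengths = {k: len(v) for k, v in state["sequences"].items()}
        passes = apply_filters(state["chains"], lengths,
                               config.thresholds())
        edges = reciprocal_edges(passes)
        fams = single_linkage_families(lengths, edges)
        state["families"] = fams
        write_edges(edges, outdir / "edges.tsv")
        write_families(fams, outdir / "families.tsv")
        done("families", n_edges=len(edges), n_families=len(fams),
             n_singletons=sum(f.is_singleton for f in fams))
    else:
        skipped("families")

    # -- align ------------------------------------------------------------
    state["_current"] = "align"
    if "align" in config.stages and "sequences" in state:
        profile = progressive_align(state["sequences"], scoring)
        state["profile"] = profile
        write_alignment(profile, outdir / "alignment.fasta")
        done("align", n_rows=len(profile.rows), n_columns=profile.n_columns)
    else:
        skipped("align")
        aln = outdir / "alignment.fasta"
        if aln.exists():
            state["profile"] = read_alignment(aln)

    # -- conserve ---------------------------------------------------------
    state["_current"] = "conserve"
    if "conserve" in config.stages and "profile" in state:
        profile: AlignmentProfile = state["profile"]
        write_conservation_table(profile, outdir / "conservation.tsv",
                                 threshold=config.conservation_threshold)
        consensus = {}
        groups = _locus_groups(state)
        for name, members in groups.items():
            consensus[name] = consensus_of(profile, members)
        with open(outdir / "consensus.fasta", "w") as fh:
            for name, seq in consensus.items():
                fh.write(f">{name}_consensus\n{seq}\n")
        done("conserve", n_columns=profile.n_columns,
             n_subfamilies=len(consensus))
    else:
        skipped("conserve")

    # -- tree -------------------------------------------------------------
    state["_current"] = "tree"
    if "tree" in config.stages and "profile" in state:
        st = bootstrap_support(state["profile"].rows,
                               n_replicates=config.bootstrap_replicates,
                               seed=config.seed,
                               correction=config.distance_correction)
        state["support_tree"] = st
        write_newick(st, outdir / "gene_tree.nwk")
        done("tree", n_replicates=st.n_replicates,
             n_bipartitions=len(st.supports))
    else:
        skipped("tree")

    # -- reconcile --------------------------------------------------------
    state["_current"] = "reconcile"
    if "reconcile" in config.stages and "support_tree" in state \
            and "species" in state:
        species: SpeciesTree = state["species"]
        out_leaf = _outgroup_leaf(state, species)
        rooted = root_with_outgroup(state["support_tree"].tree, out_leaf)
        rt = reconcile(rooted, species)
        rt.write_tsv(outdir / "reconciliation.tsv")
        summary = reconciliation_summary(rt)
        groups = _locus_groups(state)
        if groups:
            st = state["support_tree"]
            from .phylogeny import SupportTree
            rooted_support = SupportTree(rooted, st.supports,
                                         st.n_replicates)
            mono = subfamily_monophyly(rooted_support, groups)
            summary["subfamily_monophyly"] = {
                k: {"monophyletic": m, "support": s}
                for k, (m, s) in mono.items()}
        (outdir / "reconcile_summary.json").write_text(
            json.dumps(summary, indent=2))
        state["reconciled"] = rt
        done("reconcile", n_duplications=summary["n_duplications"])
    else:
        skipped("reconcile")

    # -- isoforms ---------------------------------------------------------
    state["_current"] = "isoforms"
    if "isoforms" in config.stages and "truth" in state \
            and "species" in state:
        truth = state["truth"]
        presence = {}
        for taxon in state["species"].taxa():
            rows = truth.records[truth.records.taxon == taxon]
            presence[taxon] = bool(rows.has_extra_exon.any())
        n_changes, events = parsimony_gain(state["species"], presence)
        with open(outdir / "isoform_events.tsv", "w") as fh:
            fh.write("event\tbranch_to\n")
            for e in events:
                fh.write(f"{e.kind}\t{','.join(sorted(e.branch_to))}\n")
        n_with = sum(presence.values())
        (outdir / "isoform_census.json").write_text(json.dumps(
            {"taxa_with_long_isoform": n_with,
             "taxa_without": len(presence) - n_with,
             "n_parsimony_changes": n_changes}, indent=2))
        done("isoforms", n_with=n_with, n_changes=n_changes)
    else:
        skipped("isoforms")

    # -- report -----------------------------------------------------------
    state["_current"] = "report"
    if "report" in config.stages:
        report = {"n_sequences": len(state.get("sequences", {})),
                  "families": [
                      {"family_id": f.family_id, "size": len(f.members)}
                      for f in state.get("families", [])]}
        (outdir / "report.json").write_text(json.dumps(report, indent=2))
        done("report")
    else:
        skipped("report")


def _locus_groups(state) -> dict[str, list[str]]:
    """Subfamily groups (per locus) from simulation truth, if present."""
    if "truth" not in state:
        return {}
    df = state["truth"].records
    return {f"locus_{lc}": sorted(df[df.locus == lc].sequence_id)
            for lc in sorted(df.locus.unique())}


def _outgroup_leaf(state, species: SpeciesTree) -> str:
    """Sequence id used for rooting: the outgroup taxon's (single) copy."""
    seqs = state["sequences"]
    for sid in sorted(seqs):
        if sid.rsplit("_", 1)[0] == species.outgroup_taxon:
            return sid
    if species.outgroup_taxon in seqs:
        return species.outgroup_taxon
    raise ValueError(f"no sequence for outgroup taxon "
                     f"{species.outgroup_taxon}")
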