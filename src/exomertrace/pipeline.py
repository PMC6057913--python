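"""End-to-end orchestration: simulate -> search -> hmm-iterate ->
divergence -> tree -> dollo, with a manifest, stage resume, and
machine-readable report artifacts (the dot-plot presence table, the
set-comparison battery, the supported gene tree, and the gain/loss table).

Cells of the dot plot carry three states internally (present /
not_identified / not_assessed) — absence of evidence is kept distinct from
evidence of absence — and collapse to booleans only on export. All
randomness flows from the seeds recorded in the config, so a rerun with an
identical config reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .divergence import TaxonSet, balance_by_genus, compare_sets, distance_matrix
from .hmm import iterate_search
from .io import (
    Alignment,
    PresenceAbsenceMatrix,
    SequenceRecord,
    read_newick,
    write_fasta,
    write_newick,
    write_presence_matrix,
)
from .phylo import bootstrap_support, dollo_map, group_presence, is_monophyletic
from .search import OrthologyCall, SearchConfig, classify_family
from .simulate import (
    DEFAULT_NEO_CLADE,
    SimulationConfig,
    default_species_tree,
    simulate_decoys,
    simulate_family,
    truth_table,
)

__all__ = [
    "RunConfig",
    "RunManifest",
    "DotPlot",
    "make_dotplot_table",
    "run_pipeline",
    "evaluate_rbh",
    "neo_divergence_battery",
]

STAGES = ["simulate", "search", "hmm_iter", "divergence", "tree", "dollo"]
# a stage reruns when any of these reran
STAGE_DEPS = {
    "simulate": [],
    "search": ["simulate"],
    "hmm_iter": ["simulate", "search"],
    "divergence": ["simulate", "search"],
    "tree": ["divergence"],
    "dollo": ["tree", "search"],
}


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML-serializable)."""

    outdir: str = "exomertrace_run"
    species_tree_path: str | None = None
    depth_scale: float = 1.0
    dup_rate: float = 0.05
    loss_rate: float = 0.1
    root_length: int = 200
    neo_clade: list[str] = field(default_factory=lambda: sorted(DEFAULT_NEO_CLADE))
    neo_multiplier: float = 2.0
    n_decoys: int = 20
    seed: int = 0
    family: str = "chap"
    search: dict = field(default_factory=dict)
    bit_threshold: float | None = None
    max_iterations: int = 10
    n_bootstrap: int = 100
    groups: dict[str, list[str]] | None = None
    k_min: int = 2

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def search_config(self) -> SearchConfig:
        return SearchConfig(seed=self.seed, **self.search)


@dataclass
class RunManifest:
    """Config snapshot, tool version and per-stage output checksums."""

    version: str
    config: dict
    stages: dict[str, dict[str, str]]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "version": self.version,
            "config": self.config,
            "stages": self.stages,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# dot plot


class DotPlot:
    """Three-state taxa x components table behind the dot-plot figure."""

    PRESENT = "present"
    NOT_IDENTIFIED = "not_identified"
    NOT_ASSESSED = "not_assessed"

    def __init__(self, frame: pd.DataFrame):
        self.frame = frame

    def to_presence(self) -> PresenceAbsenceMatrix:
        return PresenceAbsenceMatrix(self.frame == self.PRESENT)

    def write(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index_label="taxon")


def make_dotplot_table(
    calls: Mapping[tuple[str, str], Sequence[OrthologyCall]],
    taxa: Sequence[str],
    components: Sequence[str],
) -> DotPlot:
    """Collapse per-candidate orthology calls into the dot-plot table.

    ``calls`` maps (taxon, component) to the calls of that search; a cell
    is *present* when at least one call is positive, *not identified* when
    the search ran but produced no positive, and *not assessed* when no
    search ran for that cell.
    """
    frame = pd.DataFrame(
        DotPlot.NOT_ASSESSED, index=list(taxa), columns=list(components)
    )
    for (taxon, comp), cell_calls in calls.items():
        if any(c.status == "positive" for c in cell_calls):
            frame.at[taxon, comp] = DotPlot.PRESENT
        else:
            frame.at[taxon, comp] = DotPlot.NOT_IDENTIFIED
    return DotPlot(frame)


# ---------------------------------------------------------------------------
# reusable analysis drivers (also used by the acceptance evaluation)


def _proteomes_by_taxon(
    family_seqs: Sequence[SequenceRecord], decoys: Sequence[SequenceRecord]
) -> dict[str, list[SequenceRecord]]:
    out: dict[str, list[SequenceRecord]] = {}
    for rec in list(family_seqs) + list(decoys):
        out.setdefault(rec.taxon, []).append(rec)
    for taxon in out:
        out[taxon].sort(key=lambda r: r.id)
    return out


def _reference_taxon(family, proteomes: Mapping[str, Sequence[SequenceRecord]]) -> str:
    """The study-organism analogue: the tip with the most family sequences
    (ties to the first in species-tree tip order)."""
    best, best_n = None, -1
    for taxon in family.taxa:
        n = len(family.sequences_for(taxon))
        if n > best_n:
            best, best_n = taxon, n
    if best is None or best_n == 0:
        raise ValueError("no taxon carries any family sequence")
    return best


def evaluate_rbh(
    config: SimulationConfig,
    search_config: SearchConfig | None = None,
    family_label: str = "chap",
) -> dict:
    """Run one simulated RBH benchmark and score it against the truth.

    Simulates a family plus decoys, takes the reference taxon's family
    sequences as queries, classifies every other proteome's candidates
    bidirectionally (reverse database = the reference proteome), and
    returns the calls with precision/recall of positive calls over true
    family members vs decoys.
    """
    search_config = search_config or SearchConfig(seed=config.seed)
    family = simulate_family(config)
    if family.extinct:
        return {"extinct": True, "precision": None, "recall": None, "calls": {}}
    decoys = simulate_decoys(config)
    proteomes = _proteomes_by_taxon(family.sequences, decoys)
    ref_taxon = _reference_taxon(family, proteomes)
    queries = sorted(family.sequences_for(ref_taxon), key=lambda r: r.id)
    orthoset = {q.id for q in queries}
    reverse_dbs = {ref_taxon: proteomes[ref_taxon]}
    nonmembers = {d.id for d in decoys}

    calls: dict[str, list[OrthologyCall]] = {}
    tp = fp = fn = 0
    family_ids = {s.id for s in family.sequences}
    for taxon in family.taxa:
        if taxon == ref_taxon or taxon not in proteomes:
            continue
        taxon_calls = classify_family(
            queries,
            proteomes[taxon],
            reverse_dbs,
            orthoset,
            family=family_label,
            config=search_config,
            nonmember_ids=nonmembers,
            seed=config.seed,
        )
        calls[taxon] = taxon_calls
        positives = {c.candidate_id for c in taxon_calls if c.status == "positive"}
        members_here = {
            s.id for s in family.sequences_for(taxon)
        }
        tp += len(positives & family_ids)
        fp += len(positives - family_ids)
        fn += len(members_here - positives)
    precision = tp / (tp + fp) if (tp + fp) else None
    recall = tp / (tp + fn) if (tp + fn) else None
    return {
        "extinct": False,
        "family": family,
        "reference_taxon": ref_taxon,
        "calls": calls,
        "tp": tp, "fp": fp, "fn": fn,
        "precision": precision,
        "recall": recall,
    }


def neo_divergence_battery(family, reference_genus: str | None = None) -> dict:
    """The balanced clade-vs-preduplicate comparison on one simulation.

    Sequences with orthogroup labels containing ``.bb`` / ``.bc`` form the
    two duplicated clades; pure pre-duplication lineages form the
    preduplicate set. Both clades are genus-balanced to the reference
    taxon before comparison. Returns the two comparisons and whether the
    accelerated clade is lower with non-overlapping +/-1 SD intervals.
    """
    seqs = family.sequences
    aln = Alignment(seqs)
    matrix = distance_matrix(aln)
    bb = [s.id for s in seqs if ".bb" in family.orthogroups[s.id]]
    bc = [s.id for s in seqs if ".bc" in family.orthogroups[s.id]]
    pd_ids = [
        s.id
        for s in seqs
        if ".bb" not in family.orthogroups[s.id]
        and ".bc" not in family.orthogroups[s.id]
    ]
    if not (bb and bc and pd_ids):
        return {"informative": False}
    genus_map = {s.id: s.genus or s.taxon for s in seqs}
    if reference_genus is None:
        reference_genus = genus_map[sorted(bb)[0]]
    bb_bal = balance_by_genus(
        TaxonSet.of("BB", sorted(bb)), reference_genus, frozenset(bb), genus_map
    )
    bc_bal = balance_by_genus(
        TaxonSet.of("BC", sorted(bc)), reference_genus, frozenset(bc), genus_map
    )
    if not (bb_bal.members and bc_bal.members):
        return {"informative": False}
    pre = TaxonSet.of("PD", sorted(pd_ids))
    cmp_bb = compare_sets(matrix, bb_bal, pre)
    cmp_bc = compare_sets(matrix, bc_bal, pre)
    return {
        "informative": True,
        "bb": cmp_bb,
        "bc": cmp_bc,
        "neo_lower": cmp_bc.mean_pct_id < cmp_bb.mean_pct_id,
        "non_overlapping": not cmp_bb.overlaps(cmp_bc),
    }


# ---------------------------------------------------------------------------
# staged pipeline


def run_pipeline(config: RunConfig, resume: bool = False) -> RunManifest:
    """Execute all stages in order, writing artifacts under ``config.outdir``.

    With ``resume=True`` a stage whose outputs already exist is skipped
    unless one of its upstream stages was recomputed. Stage failures
    propagate with the stage name attached; earlier outputs stay on disk.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stage_outputs: dict[str, list[Path]] = {
        "simulate": [out / "truth_presence.tsv", out / "family.fasta",
                     out / "decoys.fasta", out / "species_tree.nwk",
                     out / "gene_tree_true.nwk"],
        "search": [out / "calls.tsv", out / "dotplot.tsv", out / "presence.tsv"],
        "hmm_iter": [out / "accepted.tsv", out / "hmm_iterations.tsv"],
        "divergence": [out / "divergence.tsv"],
        "tree": [out / "gene_tree_nj.nwk", out / "tree_checks.tsv"],
        "dollo": [out / "gainloss.tsv", out / "group_presence.tsv"],
    }
    recomputed: set[str] = set()
    state: dict = {}

    def needs_run(stage: str) -> bool:
        if not resume:
            return True
        if any(dep in recomputed for dep in STAGE_DEPS[stage]):
            return True
        return not all(p.exists() for p in stage_outputs[stage])

    for stage in STAGES:
        fn = _STAGE_FUNCS[stage]
        try:
            if needs_run(stage):
                fn(config, out, state, compute=True)
                recomputed.add(stage)
            else:
                fn(config, out, state, compute=False)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    manifest = RunManifest(
        version=__version__,
        config=asdict(config),
        stages={
            stage: {str(p.relative_to(out)): _sha256(p)
                    for p in stage_outputs[stage] if p.exists()}
            for stage in STAGES
        },
    )
    manifest.to_json(out / "manifest.json")
    return manifest


def _sim_config(config: RunConfig) -> SimulationConfig:
    if config.species_tree_path:
        tree = read_newick(Path(config.species_tree_path))
        if config.depth_scale != 1.0:
            for edge in tree.preorder_edge_iter():
                if edge.length is not None:
                    edge.length *= config.depth_scale
    else:
        tree = default_species_tree(config.depth_scale)
    return SimulationConfig(
        species_tree=tree,
        dup_rate=config.dup_rate,
        loss_rate=config.loss_rate,
        root_length=config.root_length,
        neo_clade=frozenset(config.neo_clade) if config.neo_clade else None,
        neo_multiplier=config.neo_multiplier,
        n_decoys=config.n_decoys,
        seed=config.seed,
    )


def _stage_simulate(config: RunConfig, out: Path, state: dict, compute: bool) -> None:
    sim_cfg = _sim_config(config)
    family = simulate_family(sim_cfg)
    decoys = simulate_decoys(sim_cfg)
    state["sim_cfg"] = sim_cfg
    state["family"] = family
    state["decoys"] = decoys
    if not compute:
        return
    if family.extinct:
        raise RuntimeError("simulated family went extinct; choose another seed")
    write_fasta(family.sequences, out / "family.fasta")
    write_fasta(decoys, out / "decoys.fasta")
    write_presence_matrix(truth_table(family), out / "truth_presence.tsv")
    write_newick(sim_cfg.species_tree, out / "species_tree.nwk")
    write_newick(family.gene_tree, out / "gene_tree_true.nwk")


def _stage_search(config: RunConfig, out: Path, state: dict, compute: bool) -> None:
    family = state["family"]
    decoys = state["decoys"]
    proteomes = _proteomes_by_taxon(family.sequences, decoys)
    ref_taxon = _reference_taxon(family, proteomes)
    state["ref_taxon"] = ref_taxon
    search_cfg = config.search_config()
    components = sorted(
        {family.orthogroups[s.id] for s in family.sequences_for(ref_taxon)}
    )
    state["components"] = components
    if not compute:
        # downstream stages reread artifacts from disk
        from .io import read_presence_matrix

        state["presence"] = read_presence_matrix(out / "presence.tsv")
        return
    nonmembers = {d.id for d in decoys}
    reverse_dbs = {ref_taxon: proteomes[ref_taxon]}
    all_calls: dict[tuple[str, str], list[OrthologyCall]] = {}
    rows = []
    for comp in components:
        queries = sorted(
            (s for s in family.sequences_for(ref_taxon)
             if family.orthogroups[s.id] == comp),
            key=lambda r: r.id,
        )
        orthoset = {q.id for q in queries}
        for taxon in family.taxa:
            if taxon == ref_taxon:
                member = any(
                    family.orthogroups[s.id] == comp
                    for s in family.sequences_for(taxon)
                )
                all_calls[(taxon, comp)] = [
                    OrthologyCall(q.id, "positive", 0.0, ref_taxon, q.id, 0.0,
                                  float("inf"), note="reference taxon")
                    for q in queries
                ] if member else []
                continue
            if taxon not in proteomes:
                all_calls[(taxon, comp)] = []
                continue
            calls = classify_family(
                queries, proteomes[taxon], reverse_dbs, orthoset,
                family=config.family, config=search_cfg,
                nonmember_ids=nonmembers, seed=config.seed,
            )
            all_calls[(taxon, comp)] = calls
            for c in calls:
                rows.append({
                    "component": comp, "taxon": taxon,
                    "candidate": c.candidate_id, "status": c.status,
                    "forward_evalue": c.forward_evalue,
                    "reverse_evalue": c.reverse_evalue,
                    "margin": c.margin, "reverse_db": c.reverse_db or "",
                })
    pd.DataFrame(
        rows, columns=["component", "taxon", "candidate", "status",
                       "forward_evalue", "reverse_evalue", "margin", "reverse_db"],
    ).to_csv(out / "calls.tsv", sep="\t", index=False)
    dot = make_dotplot_table(
        {k: v for k, v in all_calls.items() if v or k[0] != ref_taxon},
        family.taxa, components,
    )
    dot.write(out / "dotplot.tsv")
    presence = dot.to_presence()
    write_presence_matrix(presence, out / "presence.tsv")
    state["presence"] = presence


def _stage_hmm_iter(config: RunConfig, out: Path, state: dict, compute: bool) -> None:
    if not compute:
        return
    family = state["family"]
    decoys = state["decoys"]
    ref_taxon = state["ref_taxon"]
    comp = state["components"][0]
    seed_ids = sorted(
        s.id for s in family.sequences
        if family.orthogroups[s.id] == comp and s.taxon == ref_taxon
    )
    # seed with the reference sequences plus their closest relatives
    seed_rows = [s for s in family.sequences if s.id in seed_ids]
    if len(seed_rows) < 2:
        extra = sorted(
            (s for s in family.sequences if family.orthogroups[s.id] == comp
             and s.id not in seed_ids),
            key=lambda r: r.id,
        )[: 2 - len(seed_rows)]
        seed_rows += extra
    if len(seed_rows) < 2:
        pd.DataFrame(columns=["id"]).to_csv(out / "accepted.tsv", sep="\t", index=False)
        pd.DataFrame().to_csv(out / "hmm_iterations.tsv", sep="\t", index=False)
        return
    seed_aln = Alignment(sorted(seed_rows, key=lambda r: r.id))
    proteome_pool = sorted(
        list(family.sequences) + list(decoys), key=lambda r: r.id
    )
    ref_proteome = [r for r in proteome_pool if r.taxon == ref_taxon]
    result = iterate_search(
        seed_aln, proteome_pool, ref_proteome,
        config=config.search_config(),
        bit_threshold=config.bit_threshold,
        max_iterations=config.max_iterations,
        seed=config.seed,
    )
    pd.DataFrame({"id": sorted(result.accepted)}).to_csv(
        out / "accepted.tsv", sep="\t", index=False
    )
    pd.DataFrame(result.log).to_csv(out / "hmm_iterations.tsv", sep="\t", index=False)
    state["hmm_state"] = result


def _stage_divergence(config: RunConfig, out: Path, state: dict, compute: bool) -> None:
    family = state["family"]
    battery = neo_divergence_battery(family)
    state["battery"] = battery
    if not compute:
        return
    if not battery["informative"]:
        pd.DataFrame(
            columns=["set_a", "set_b", "n_pairs", "mean_pct_id", "sd", "overlap_flag"]
        ).to_csv(out / "divergence.tsv", sep="\t", index=False)
        return
    rows = []
    for cmp_ in (battery["bb"], battery["bc"]):
        rows.append({
            "set_a": cmp_.set_a, "set_b": cmp_.set_b, "n_pairs": cmp_.n_pairs,
            "mean_pct_id": round(cmp_.mean_pct_id, 6),
            "sd": round(cmp_.sd, 6) if cmp_.sd is not None else "",
            "overlap_flag": battery["bb"].overlaps(battery["bc"]),
        })
    pd.DataFrame(rows).to_csv(out / "divergence.tsv", sep="\t", index=False)


def _stage_tree(config: RunConfig, out: Path, state: dict, compute: bool) -> None:
    if not compute:
        return
    family = state["family"]
    if len(family.sequences) < 4:
        (out / "gene_tree_nj.nwk").write_text(";\n")
        pd.DataFrame().to_csv(out / "tree_checks.tsv", sep="\t", index=False)
        return
    aln = Alignment(sorted(family.sequences, key=lambda r: r.id))
    tree = bootstrap_support(aln, n_replicates=config.n_bootstrap, seed=config.seed)
    write_newick(tree, out / "gene_tree_nj.nwk")
    checks = []
    bb = sorted(s.id for s in family.sequences if ".bb" in family.orthogroups[s.id])
    bc = sorted(s.id for s in family.sequences if ".bc" in family.orthogroups[s.id])
    pre = sorted(
        s.id for s in family.sequences
        if ".bb" not in family.orthogroups[s.id]
        and ".bc" not in family.orthogroups[s.id]
    )
    for name, tips in (("BB", bb), ("BC", bc)):
        if len(tips) >= 2 and pre:
            mono, support = is_monophyletic(tree, tips, pre[:1])
            checks.append({"clade": name, "monophyletic": mono,
                           "support": support if support is not None else ""})
    pd.DataFrame(checks).to_csv(out / "tree_checks.tsv", sep="\t", index=False)


def _stage_dollo(config: RunConfig, out: Path, state: dict, compute: bool) -> None:
    if not compute:
        return
    presence = state["presence"]
    sim_cfg = state["sim_cfg"]
    tree = sim_cfg.species_tree
    groups = config.groups or _default_groups(presence.taxa)
    collapsed, exceptions = group_presence(presence, groups, k_min=config.k_min)
    write_presence_matrix(collapsed, out / "group_presence.tsv")
    rows = []
    for comp in presence.components:
        gl = dollo_map(tree, presence.column(comp), component=comp)
        rows.append({
            "component": comp,
            "gain_node": ";".join(gl.gain) if gl.gain else "",
            "loss_edges": "|".join(";".join(l) for l in gl.losses),
            "n_losses": gl.n_losses,
            "many_losses_flag": gl.many_losses_flag,
        })
    for group, comp, taxon in exceptions:
        rows.append({
            "component": comp, "gain_node": f"single-representative:{group}",
            "loss_edges": taxon, "n_losses": "", "many_losses_flag": "",
        })
    pd.DataFrame(rows).to_csv(out / "gainloss.tsv", sep="\t", index=False)


def _default_groups(taxa: Sequence[str]) -> dict[str, list[str]]:
    groups: dict[str, list[str]] = {}
    for t in taxa:
        groups.setdefault(t.rstrip("0123456789") or t, []).append(t)
    return groups


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "search": _stage_search,
    "hmm_iter": _stage_hmm_iter,
    "divergence": _stage_divergence,
    "tree": _stage_tree,
    "dollo": _stage_dollo,
}
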