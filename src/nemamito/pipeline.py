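"""End-to-end pipeline stages and the run manifest.

Stages run in order ingest -> composition -> partition -> rates ->
saturation -> traits, each writing tidy TSVs into the output directory plus
a JSON manifest recording the configuration, seed, thresholds and input
digests.  Failures localized to one gene or species degrade to recorded
missing values rather than aborting the run; every summary carries its
exclusion counts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .alignment import AlignmentBlock, GENE_ORDER, concatenate, check_reading_frame, read_alignment, write_concatenated
from .composition import clade_summary, codon_skew_matrix, composition_table, genome_summary
from .gencode import genetic_code
from .genomes import (
    GenomeParseError,
    Mitogenome,
    attach_traits,
    extract_pcgs,
    orient_to_cox1,
    read_genbank,
    read_trait_table,
    validate_completeness,
    write_gene_fastas,
)
from .rates import MIN_CODONS, rates_table
from .saturation import saturation_test
from .simulate import OUTGROUP_IDS, SyntheticConfig, build_dataset
from .stats import run_battery

STAGES = ("ingest", "composition", "partition", "rates", "saturation", "traits")


@dataclass
class RunConfig:
    """Configuration for a pipeline run (loadable from YAML)."""

    genomes_dir: str
    alignments_dir: str
    trait_table: str
    outdir: str
    seed: int
    newick: str | None = None
    outgroup_ids: tuple[str, ...] = OUTGROUP_IDS
    table_id: int = 5
    min_codons: int = MIN_CODONS
    n_reps: int = 500
    z_not_saturated: float = -6.0
    z_saturated: float = -2.0
    min_group_size: int = 2
    stages: tuple[str, ...] = STAGES

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValueError(f"config {path}: expected a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"config {path}: unknown keys {sorted(unknown)}")
        missing = {"genomes_dir", "alignments_dir", "trait_table", "outdir", "seed"} - set(raw)
        if missing:
            raise ValueError(f"config {path}: missing required keys {sorted(missing)}")
        for key in ("outgroup_ids", "stages"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _newick_order(path: str | Path) -> list[str]:
    """Leaf names in the order they appear in a Newick file."""
    text = Path(path).read_text()
    out, token = [], []
    for ch in text:
        if ch in "(),;:\n\t ":
            if token:
                name = "".join(token)
                if not name.replace(".", "").replace("-", "").isdigit():
                    out.append(name)
                token = []
        else:
            token.append(ch)
    return out


@dataclass
class RunState:
    config: RunConfig
    genomes: list[Mitogenome] = field(default_factory=list)
    cdss: dict[str, list] = field(default_factory=dict)       # species -> CodingSequences
    blocks: list[AlignmentBlock] = field(default_factory=list)
    clade_of: dict[str, str] = field(default_factory=dict)
    notes: dict[str, list[str]] = field(default_factory=dict)

    def note(self, stage: str, message: str) -> None:
        self.notes.setdefault(stage, []).append(message)


def stage_ingest(state: RunState) -> None:
    cfg = state.config
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genomes: list[Mitogenome] = []
    for path in sorted(Path(cfg.genomes_dir).glob("*.gb*")):
        genomes.extend(read_genbank(path))
    traits = read_trait_table(cfg.trait_table)
    attach_traits(genomes, traits)
    code = genetic_code(cfg.table_id)
    oriented = []
    completeness_rows = []
    for g in genomes:
        try:
            g = orient_to_cox1(g)
        except GenomeParseError as exc:
            state.note("ingest", f"not oriented: {exc}")
        rep = validate_completeness(g)
        completeness_rows.append(
            {"species_id": g.id, "n_pcgs": rep.n_pcgs, "n_trnas": rep.n_trnas,
             "n_rrnas": rep.n_rrnas, "circularized": rep.circularized,
             "is_complete": rep.is_complete}
        )
        try:
            state.cdss[g.id] = extract_pcgs(g, code)
        except GenomeParseError as exc:
            state.note("ingest", f"extraction failed: {exc}")
            state.cdss[g.id] = []
        oriented.append(g)
    state.genomes = oriented
    state.clade_of = {g.id: g.taxonomy.get("suborder") for g in oriented}
    pd.DataFrame(completeness_rows).to_csv(outdir / "completeness.tsv", sep="\t", index=False)
    all_cdss = [c for cs in state.cdss.values() for c in cs]
    write_gene_fastas(all_cdss, outdir / "extracted_cds")


def stage_composition(state: RunState) -> None:
    cfg = state.config
    outdir = Path(cfg.outdir)
    records = []
    for g in state.genomes:
        cdss = state.cdss.get(g.id, [])
        if not cdss:
            state.note("composition", f"{g.id}: skipped, no extracted PCGs")
            continue
        records.append(genome_summary(g, cdss))
    order = _newick_order(cfg.newick) if cfg.newick else None
    composition_table(records, order).to_csv(outdir / "composition.tsv", sep="\t")
    codon_skew_matrix(records, order).to_csv(outdir / "codon_skews.tsv", sep="\t")
    labels = {sp: clade for sp, clade in state.clade_of.items()}
    rows = []
    for summary in clade_summary(records, labels):
        for metric, ms in summary.metrics.items():
            rows.append(
                {"group": summary.group, "metric": metric, "n": ms.n,
                 "mean": ms.mean, "stdev": ms.stdev, "min": ms.min,
                 "max": ms.max, "n_excluded": ms.n_excluded}
            )
    pd.DataFrame(rows).to_csv(outdir / "clade_summary.tsv", sep="\t", index=False)


def stage_partition(state: RunState) -> None:
    cfg = state.config
    outdir = Path(cfg.outdir)
    code = genetic_code(cfg.table_id)
    blocks = []
    frame_rows = []
    for gene in GENE_ORDER:
        path = Path(cfg.alignments_dir) / f"{gene}.fasta"
        if not path.exists():
            state.note("partition", f"{gene}: alignment missing")
            continue
        block = read_alignment(path, gene=gene)
        blocks.append(block)
        for taxon, stops in check_reading_frame(block, code).items():
            frame_rows.append(
                {"gene": gene, "taxon": taxon, "n_internal_stops": len(stops),
                 "stop_codon_indices": ";".join(map(str, stops))}
            )
    state.blocks = blocks
    pd.DataFrame(frame_rows).to_csv(outdir / "frame_report.tsv", sep="\t", index=False)
    if blocks:
        concat = concatenate(blocks)
        write_concatenated(concat, outdir / "pcg_genome.fasta", outdir / "partitions.tsv")


def stage_rates(state: RunState) -> None:
    cfg = state.config
    outdir = Path(cfg.outdir)
    code = genetic_code(cfg.table_id)
    df = rates_table(state.blocks, cfg.outgroup_ids, code, cfg.min_codons)
    df.to_csv(outdir / "rates.tsv", sep="\t", index=False)


def stage_saturation(state: RunState) -> None:
    cfg = state.config
    outdir = Path(cfg.outdir)
    rows = []
    clades = sorted({c for c in state.clade_of.values() if c})
    counter = 0
    for block in state.blocks:
        for clade in clades:
            taxa = [t for t in block.taxa
                    if state.clade_of.get(t) == clade]
            for position in ("1", "2", "3"):
                counter += 1
                try:
                    res = saturation_test(
                        block, position, taxa,
                        n_reps=cfg.n_reps, seed=cfg.seed + counter, clade=clade,
                        z_not_saturated=cfg.z_not_saturated,
                        z_saturated=cfg.z_saturated,
                    )
                except ValueError as exc:
                    state.note("saturation", f"{block.gene}/{clade}/pos{position}: {exc}")
                    continue
                rows.append(
                    {"clade": res.clade, "gene": res.gene,
                     "codon_position": res.codon_position, "n_taxa": res.n_taxa,
                     "n_resolved_sites": res.n_resolved_sites,
                     "iss_obs": res.iss_obs, "null_mean": res.null_mean,
                     "null_sd": res.null_sd, "z": res.z, "p": res.p_one_sided,
                     "verdict": res.verdict, "n_reps": res.n_reps, "seed": res.seed}
                )
    pd.DataFrame(
        rows,
        columns=["clade", "gene", "codon_position", "n_taxa", "n_resolved_sites",
                 "iss_obs", "null_mean", "null_sd", "z", "p", "verdict",
                 "n_reps", "seed"],
    ).to_csv(outdir / "saturation.tsv", sep="\t", index=False)


def stage_traits(state: RunState) -> None:
    cfg = state.config
    outdir = Path(cfg.outdir)
    comp_path = outdir / "composition.tsv"
    if not comp_path.exists():
        raise FileNotFoundError(
            "traits stage needs composition.tsv; run the composition stage first"
        )
    comp = pd.read_csv(comp_path, sep="\t", index_col="species_id")
    metrics = [c for c in (
        "genome_length", "pcg_total_length", "pcg_proportion",
        "genome_pct_gc", "pcg_pct_gc", "genome_gc_skew", "pcg_gc_skew",
    ) if c in comp.columns]
    merged = comp[metrics].copy()
    rates_path = outdir / "rates.tsv"
    if rates_path.exists():
        rates = pd.read_csv(rates_path, sep="\t")
        per_species = rates.groupby("species_id")[["dN_mean", "dS_mean", "omega"]].mean()
        per_species.columns = ["dN", "dS", "dNdS"]
        merged = merged.join(per_species)
        metrics += ["dN", "dS", "dNdS"]
    else:
        state.note("traits", "rates stage outputs absent; testing composition metrics only")
    traits = read_trait_table(cfg.trait_table)
    label_cols = {}
    for rank in ("class", "subclass", "order", "suborder", "infraorder", "family", "genus"):
        label_cols[rank] = {sp: tax.get(rank) for sp, (tax, _) in traits.items()}
    for trait in ("feeding_habit", "habitat", "reproduction"):
        label_cols[trait] = {sp: tr.get(trait) for sp, (_, tr) in traits.items()}
    for name, mapping in label_cols.items():
        merged[name] = [mapping.get(sp) for sp in merged.index]
    groupings = ["feeding_habit", "habitat", "reproduction",
                 "subclass", "order", "suborder", "infraorder", "family", "genus"]
    tests, dunn = run_battery(merged, metrics, groupings, block="suborder")
    tests.to_csv(outdir / "kw_tests.tsv", sep="\t", index=False)
    dunn.to_csv(outdir / "dunn_tests.tsv", sep="\t", index=False)


_STAGE_FUNCS = {
    "ingest": stage_ingest,
    "composition": stage_composition,
    "partition": stage_partition,
    "rates": stage_rates,
    "saturation": stage_saturation,
    "traits": stage_traits,
}


def run(config: RunConfig) -> Path:
    """Run the configured stages in order; returns the output directory.

    Writes ``manifest.json`` recording the package version, full config,
    stage list, input digests and per-stage notes (exclusions, skips).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    state = RunState(config=config)
    executed = []
    for stage in STAGES:
        if stage not in config.stages:
            continue
        _STAGE_FUNCS[stage](state)
        executed.append(stage)
    digests = {}
    for path in sorted(Path(config.genomes_dir).glob("*.gb*")):
        digests[str(path)] = _sha256(path)
    for path in sorted(Path(config.alignments_dir).glob("*.fasta")):
        digests[str(path)] = _sha256(path)
    trait_path = Path(config.trait_table)
    if trait_path.exists():
        digests[str(trait_path)] = _sha256(trait_path)
    manifest = {
        "package": "nemamito",
        "version": __version__,
        "stages": executed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "input_digests": digests,
        "notes": state.notes,
        "metadata": {
            "rate_estimator": "NG86-type counting with Jukes-Cantor correction",
            "saturation_null": "Monte-Carlo full-saturation (pooled-frequency multinomial)",
            "genome_skew_strand": "post COX1 orientation, stored (+) strand",
            "dnds_aggregation": "ratio of outgroup-averaged dN and dS",
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return outdir


def simulate_dataset(seed: int, outdir: str | Path, **overrides) -> SyntheticConfig:
    """Generate a synthetic dataset (convenience wrapper for the CLI)."""
    cfg = SyntheticConfig(seed=seed, **overrides)
    build_dataset(cfg, outdir)
    return cfg
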