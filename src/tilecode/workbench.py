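"""I/O, run configuration and the end-to-end pipeline.

All tabular interchange is tab-separated UTF-8 text with ``#`` comment
lines; sequences travel as FASTA. Every output of :func:`run_pipeline` is a
pure function of the inputs and the config (seed included), so a rerun with
the same config is bit-identical — no timestamps are embedded in outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from . import diagnostics, quantification, screen_stats
from .probe_design import ArrayLayout, ConstructRecord, Probe, build_array_layout
from .synthetic_data import (
    IntensityTable,
    ScreenScenario,
    random_constructs,
    simulate_negative_selection,
)

logger = logging.getLogger("tilecode")

MANIFEST_COLUMNS = ("construct_id", "gene_symbol", "barcode_seq", "hairpin_stem")


def configure_logging(level: str = "INFO", log_file: str | Path | None = None) -> None:
    """Console (and optional file) logging; no timestamps, for reproducible logs."""
    root = logging.getLogger("tilecode")
    root.setLevel(getattr(logging, level.upper()))
    root.handlers.clear()
    fmt = logging.Formatter("%(levelname)s %(message)s")
    sh = logging.StreamHandler()
    sh.setFormatter(fmt)
    root.addHandler(sh)
    if log_file is not None:
        fh = logging.FileHandler(log_file, mode="w")
        fh.setFormatter(fmt)
        root.addHandler(fh)


# ---------------------------------------------------------------------------
# Manifests


def read_manifest(path: str | Path) -> list[ConstructRecord]:
    """Read a construct manifest from TSV or FASTA.

    TSV needs columns construct_id and barcode_seq (gene_symbol and
    hairpin_stem optional); FASTA records give barcode-only constructs with
    the record id as construct_id. Duplicate IDs and malformed rows are
    rejected with the offending line/record named.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    if path.suffix.lower() in (".fa", ".fasta", ".fna"):
        records = []
        seen = set()
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in seen:
                raise ValueError(f"duplicate construct_id {rec.id!r} in {path}")
            seen.add(rec.id)
            records.append(ConstructRecord(construct_id=rec.id, barcode_seq=str(rec.seq)))
        if not records:
            raise ValueError(f"no FASTA records in {path}")
        logger.info("read %d barcode-only constructs from %s (stems absent)", len(records), path)
        return records

    records = []
    seen: dict[str, int] = {}
    header: list[str] | None = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if header is None:
                header = [h.strip() for h in parts]
                missing = {"construct_id", "barcode_seq"} - set(header)
                if missing:
                    raise ValueError(f"{path}:{lineno}: missing column(s) {sorted(missing)}")
                continue
            if len(parts) != len(header):
                raise ValueError(
                    f"{path}:{lineno}: {len(parts)} field(s), expected {len(header)}"
                )
            row = dict(zip(header, (p.strip() for p in parts)))
            cid = row["construct_id"]
            if cid in seen:
                raise ValueError(
                    f"{path}:{lineno}: duplicate construct_id {cid!r} (first at line {seen[cid]})"
                )
            seen[cid] = lineno
            try:
                records.append(ConstructRecord(
                    construct_id=cid,
                    barcode_seq=row["barcode_seq"],
                    hairpin_stem=row.get("hairpin_stem", ""),
                    gene_symbol=row.get("gene_symbol", ""),
                ))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    if not records:
        raise ValueError(f"no construct rows in {path}")
    return records


def write_manifest(records: Sequence[ConstructRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(MANIFEST_COLUMNS) + "\n")
        for r in records:
            fh.write(f"{r.construct_id}\t{r.gene_symbol}\t{r.barcode_seq}\t{r.hairpin_stem}\n")


# ---------------------------------------------------------------------------
# Layouts


def write_probe_table(layout: ArrayLayout, path: str | Path) -> None:
    df = layout.frame().drop(columns="position").reset_index()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# n_subarrays\t{layout.n_subarrays}\n")
        fh.write(f"# tiling_reps\t{layout.tiling_reps}\n")
        fh.write(f"# hh_reps\t{layout.hh_reps}\n")
        neg = ",".join(sorted(layout.negative_construct_ids))
        fh.write(f"# negative_construct_ids\t{neg}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_probe_table(path: str | Path) -> ArrayLayout:
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition("\t")
            meta[key.strip()] = val.strip()
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"construct_id": str})
    probes = [
        Probe(
            probe_id=r.probe_id, construct_id=r.construct_id, kind=r.kind,
            offset=int(r.offset), length=int(r.length), sequence=r.sequence,
            replicate=int(r.replicate), subarray=int(r.subarray),
        )
        for r in df.itertuples(index=False)
    ]
    neg = frozenset(x for x in meta.get("negative_construct_ids", "").split(",") if x)
    return ArrayLayout(
        probes=probes,
        n_subarrays=int(meta.get("n_subarrays", df["subarray"].max())),
        tiling_reps=int(meta.get("tiling_reps", 3)),
        hh_reps=int(meta.get("hh_reps", 4)),
        negative_construct_ids=neg,
    )


def write_probe_fasta(layout: ArrayLayout, path: str | Path) -> None:
    """Unique probe sequences (one per probe template) as FASTA."""
    df = layout.frame().reset_index()
    uniq = df.drop_duplicates(subset=["construct_id", "kind", "offset"])
    with open(path, "w", encoding="utf-8") as fh:
        for r in uniq.itertuples(index=False):
            name = r.probe_id.split(":r")[0]
            fh.write(f">{name} kind={r.kind} offset={r.offset}\n{r.sequence}\n")


# ---------------------------------------------------------------------------
# Intensity tables


def write_intensity_table(table: IntensityTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sid, row in table.samples.iterrows():
            fh.write(f"# sample\t{sid}\trole={row['role']}\treplicate={row['replicate']}\n")
        table.values.rename_axis("probe_id").to_csv(fh, sep="\t")


def read_intensity_table(path: str | Path, layout: ArrayLayout | None = None) -> IntensityTable:
    """Read an intensity TSV, validating probes against a layout if given.

    With a layout, unknown probe IDs are rejected and the presence of
    negative-control features is verified (they anchor the background
    estimate); negative signal values are always rejected.
    """
    path = Path(path)
    meta = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            parts = line[1:].strip().split("\t")
            if parts[0] != "sample":
                continue
            entry = {"sample_id": parts[1]}
            for kv in parts[2:]:
                k, _, v = kv.partition("=")
                entry[k] = v
            meta.append(entry)
    values = pd.read_csv(path, sep="\t", comment="#", index_col="probe_id")
    if not meta:
        meta = [{"sample_id": c, "role": "unknown", "replicate": 1} for c in values.columns]
    samples = pd.DataFrame(meta).set_index("sample_id")
    samples["replicate"] = samples["replicate"].astype(int)
    samples = samples.loc[values.columns]
    if (values.to_numpy() < 0).any():
        bad = values.index[(values < 0).any(axis=1)][0]
        raise ValueError(f"negative signal value at probe {bad!r}")
    if layout is not None:
        known = set(layout.sample_features().index)
        unknown = set(values.index) - known
        if unknown:
            raise ValueError(f"unknown probe_id(s): {sorted(unknown)[:5]}")
        neg = set(layout.negative_probe_ids()) & set(values.index)
        if layout.negative_construct_ids and not neg:
            raise ValueError("no negative controls in the intensity table")
    return IntensityTable(values=values, samples=samples)


# ---------------------------------------------------------------------------
# Run configuration and end-to-end pipeline


@dataclass
class RunConfig:
    """Everything one reproducible screen run depends on."""

    out_dir: str = "tilecode_run"
    manifest: str | None = None       # path; None -> synthesize constructs
    n_constructs: int = 100
    n_negatives: int = 11
    n_depleted: int = 10
    log2_effect: float = -2.0
    affinity_sigma: float = 1.0
    overlap_rho: float = 0.6
    noise_cv: float = 0.2
    background_level: float = 20.0
    saturation_smax: float | None = None
    n_replicates: int = 3
    abundance_scale: float = 1000.0
    k_fold_screen: float = 10.0
    min_probes: int = 2
    min_ratio_values: int = 4
    alpha: float = 0.05
    use_adjusted_p: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Design -> simulate -> quantify -> screen -> diagnose, all on disk.

    Returns a summary dict (also written as run_manifest.json). Every stage
    failure is re-raised with the stage named.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    configure_logging(log_file=out / "run.log")
    logger.info("run starts: seed=%d out=%s", config.seed, out)
    stage = "design"
    try:
        if config.manifest is not None:
            constructs = read_manifest(config.manifest)
        else:
            constructs = random_constructs(config.n_constructs, seed=config.seed)
        negatives = random_constructs(
            config.n_negatives, seed=config.seed + 10_000, prefix="NEG"
        )
        layout = build_array_layout(constructs, negatives)
        write_probe_table(layout, out / "layout.tsv")
        write_probe_fasta(layout, out / "probes.fasta")
        write_manifest(constructs, out / "constructs.tsv")

        stage = "simulate"
        ids = [c.construct_id for c in constructs]
        depleted = ids[: config.n_depleted]
        scenario = ScreenScenario(
            depleted_ids=frozenset(depleted),
            log2_effect={c: config.log2_effect for c in depleted},
            affinity_sigma=config.affinity_sigma,
            overlap_rho=config.overlap_rho,
            noise_cv=config.noise_cv,
            background_level=config.background_level,
            saturation_smax=config.saturation_smax,
            n_replicates=config.n_replicates,
            abundance_scale=config.abundance_scale,
            seed=config.seed,
        )
        table, truth = simulate_negative_selection(layout, scenario)
        write_intensity_table(table, out / "intensities.tsv")
        truth.to_csv(out / "ground_truth.tsv", sep="\t")

        stage = "quantify"
        agg, bg = quantification.quantify_screen(
            table, layout,
            k_fold=config.k_fold_screen,
            min_probes=config.min_probes,
            min_ratio_values=config.min_ratio_values,
        )
        agg.constructs.to_csv(out / "construct_results.tsv", sep="\t")
        agg.drop_log.to_csv(out / "drop_log.tsv", sep="\t", index=False)

        stage = "screen"
        res = screen_stats.screen_results(agg)
        calls = screen_stats.call_hits(
            res, alpha=config.alpha, use_adjusted=config.use_adjusted_p
        )
        res.to_csv(out / "screen_stats.tsv", sep="\t")
        calls.hits.to_csv(out / "hits.tsv", sep="\t")
        calls.volcano.to_csv(out / "volcano.tsv", sep="\t")

        stage = "diagnose"
        mat = diagnostics.tzero_position_matrix(table, layout)
        ca = diagnostics.correspondence_analysis(mat)
        ca.row_coords.to_csv(out / "ca_rows.tsv", sep="\t")
        ca.col_coords.to_csv(out / "ca_cols.tsv", sep="\t")
        wide = diagnostics.ratio_table_to_wide(agg.kept_ratios)
        sim = diagnostics.position_correlation(wide)
        sim.r2_matrix.to_csv(out / "r2_matrix.tsv", sep="\t")
        sim.grouped.to_csv(out / "r2_grouped.tsv", sep="\t")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    outputs = sorted(p.name for p in out.glob("*.tsv"))
    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "n_constructs": len(constructs),
        "n_analyzable": int(len(agg.constructs)),
        "n_hits": int(len(calls.hits)),
        "total_inertia": ca.total_inertia,
        "outputs": {name: _sha256(out / name) for name in outputs},
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("run finished: %d analyzable constructs, %d hits",
                manifest["n_analyzable"], manifest["n_hits"])
    return manifest
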