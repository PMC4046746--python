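"""End-to-end pipeline orchestration from a single YAML config.

Stages run in dependency order — simulate, buildref, clean, map,
saturation, dge, enrich, report — with every output written as TSV/JSON
under one output directory and a manifest recording seeds, parameters and
input checksums.  Stages whose outputs already exist for the same config
hash are skipped, so a rerun of an unchanged config is a no-op and a
changed seed reruns the simulated stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .enrichment import hypergeom_enrich, read_annotation_tsv, write_enrichment_tsv
from .mapping import gene_counts, map_tags, saturation_curve
from .processing import DEFAULT_BIN_EDGES, TagLibrary, abundance_distribution, clean_fastq
from .reference import TranscriptSet, build_virtual_tag_db, uniqueness_report, write_tag_db_tsv
from .stats import (
    DEFAULT_FDR_MAX,
    DEFAULT_MIN_ABS_LOG2,
    call_degs,
    classify_phase,
    de_table,
    format_ratio,
)
from .synthetic import generate_transcriptome, sample_expression, simulate_tag_library

log = logging.getLogger("dgetag")

_DEFAULT_PARAMS = {
    "max_mismatch": 1,
    "fdr_max": DEFAULT_FDR_MAX,
    "min_abs_log2": DEFAULT_MIN_ABS_LOG2,
    "q_max": 0.05,
    "zero_floor": 1.0,
    "bin_edges": list(DEFAULT_BIN_EDGES),
    "saturation_grid": None,
    "tag_offset": 0,
}

_DEFAULT_SIMULATE = {
    "n_genes": 2000,
    "mean_length": 560,
    "catg_free_fraction": 0.05,
    "conditions": ["control", "1h", "5h", "24h"],
    "de_fraction": 0.05,
    "effect_log2": 2.0,
    "dispersion": 2.5,
    "depth": 100000,
    "error_rate": 0.01,
    "adaptor_only_rate": 0.06,
    "n_read_rate": 0.025,
}


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    Either a ``simulate`` block (synthetic study) or explicit ``reference``
    FASTA and per-sample FASTQ/tag-TSV paths must be provided; ``control``
    names the baseline sample compared pairwise against every other.
    """

    outdir: Path
    seed: int = 0
    simulate: dict | None = None
    reference: Path | None = None
    samples: dict[str, Path] = field(default_factory=dict)
    control: str | None = None
    annotation: Path | None = None
    params: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw, base=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, base: Path = Path(".")) -> "RunConfig":
        if "outdir" not in raw:
            raise ValueError("config must set 'outdir'")
        params = dict(_DEFAULT_PARAMS)
        params.update(raw.get("params") or {})
        simulate = raw.get("simulate")
        if simulate is not None:
            merged = dict(_DEFAULT_SIMULATE)
            merged.update(simulate)
            simulate = merged
        cfg = cls(
            outdir=base / raw["outdir"],
            seed=int(raw.get("seed", 0)),
            simulate=simulate,
            reference=(base / raw["reference"]) if raw.get("reference") else None,
            samples={k: base / v for k, v in (raw.get("samples") or {}).items()},
            control=raw.get("control"),
            annotation=(base / raw["annotation"]) if raw.get("annotation") else None,
            params=params,
        )
        if cfg.simulate is None and cfg.reference is None:
            raise ValueError("config needs either a 'simulate' block or a 'reference' FASTA")
        for thr in ("fdr_max", "min_abs_log2", "q_max"):
            if cfg.params[thr] <= 0:
                raise ValueError(f"threshold {thr} must be positive")
        return cfg

    def to_jsonable(self) -> dict:
        return {
            "outdir": str(self.outdir),
            "seed": self.seed,
            "simulate": self.simulate,
            "reference": str(self.reference) if self.reference else None,
            "samples": {k: str(v) for k, v in self.samples.items()},
            "control": self.control,
            "annotation": str(self.annotation) if self.annotation else None,
            "params": self.params,
        }

    def digest(self) -> str:
        blob = json.dumps(self.to_jsonable(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class PipelineError(RuntimeError):
    pass


class _Manifest:
    def __init__(self, path: Path, config: RunConfig):
        self.path = path
        self.config_digest = config.digest()
        if path.exists():
            with open(path) as fh:
                self.data = json.load(fh)
            if self.data.get("config_digest") != self.config_digest:
                self.data = self._fresh(config)
        else:
            self.data = self._fresh(config)

    def _fresh(self, config: RunConfig) -> dict:
        return {
            "version": __version__,
            "config_digest": self.config_digest,
            "seed": config.seed,
            "config": config.to_jsonable(),
            "stages": {},
            "input_checksums": {},
        }

    def stage_done(self, name: str, outputs: list[Path]) -> bool:
        return name in self.data["stages"] and all(p.exists() for p in outputs)

    def record(self, name: str, outputs: list[Path], elapsed: float) -> None:
        self.data["stages"][name] = {
            "outputs": [str(p) for p in outputs],
            "elapsed_s": round(elapsed, 3),
        }
        self.save()

    def save(self) -> None:
        with open(self.path, "w") as fh:
            json.dump(self.data, fh, indent=2)
            fh.write("\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages; return the manifest dict.

    Missing inputs fail fast naming the stage; a stage failure leaves
    earlier outputs in place.  Two runs with the same config and seed
    produce byte-identical TSVs.
    """
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out / "manifest.json", config)

    def stage(name, outputs, fn):
        if manifest.stage_done(name, outputs):
            log.info("stage %s: up to date, skipped", name)
            return
        t0 = time.monotonic()
        log.info("stage %s: running", name)
        fn()
        manifest.record(name, outputs, time.monotonic() - t0)
        log.info("stage %s: done (%.2fs)", name, time.monotonic() - t0)

    # -- simulate --------------------------------------------------------
    if config.simulate is not None:
        sim = config.simulate
        conditions = list(sim["conditions"])
        ref_fa = out / "reference.fasta"
        truth_tsv = out / "truth.tsv"
        fastqs = {c: out / f"{c}.fastq" for c in conditions}

        def do_simulate():
            transcripts = generate_transcriptome(
                sim["n_genes"],
                sim["mean_length"],
                seed=config.seed,
                catg_free_fraction=sim["catg_free_fraction"],
            )
            truth = sample_expression(
                transcripts,
                conditions,
                de_fraction=sim["de_fraction"],
                effect_log2=sim["effect_log2"],
                dispersion=sim["dispersion"],
                seed=config.seed + 1,
            )
            transcripts.to_fasta(ref_fa)
            truth.to_tsv(truth_tsv)
            for i, cond in enumerate(conditions):
                reads = simulate_tag_library(
                    transcripts,
                    truth,
                    cond,
                    depth=sim["depth"],
                    error_rate=sim["error_rate"],
                    adaptor_only_rate=sim["adaptor_only_rate"],
                    n_read_rate=sim["n_read_rate"],
                    seed=config.seed + 10 + i,
                )
                reads.to_fastq(fastqs[cond])

        stage("simulate", [ref_fa, truth_tsv, *fastqs.values()], do_simulate)
        reference_path = ref_fa
        samples = fastqs
        control = config.control or conditions[0]
    else:
        reference_path = config.reference
        samples = dict(config.samples)
        control = config.control or (next(iter(samples)) if samples else None)

    if not reference_path.exists():
        raise PipelineError(f"stage buildref: missing reference {reference_path}")
    manifest.data["input_checksums"][str(reference_path)] = _sha256(reference_path)

    # -- buildref --------------------------------------------------------
    tagdb_tsv = out / "tagdb.tsv"
    uniq_json = out / "tagdb_summary.json"
    transcripts = TranscriptSet.from_fasta(reference_path)
    index = build_virtual_tag_db(transcripts)

    def do_buildref():
        write_tag_db_tsv(index, tagdb_tsv)
        with open(uniq_json, "w") as fh:
            json.dump(uniqueness_report(index), fh, indent=2)
            fh.write("\n")

    stage("buildref", [tagdb_tsv, uniq_json], do_buildref)

    # -- clean / map / saturation per sample -----------------------------
    libs: dict[str, TagLibrary] = {}
    counts = {}
    for name, path in samples.items():
        if not path.exists():
            raise PipelineError(f"stage clean: missing input {path} for sample {name}")
        if path.suffix in (".fastq", ".fq") or str(path).endswith((".fastq.gz", ".fq.gz")):
            lib = clean_fastq(path, sample_id=name, tag_offset=config.params["tag_offset"])
        else:
            lib = TagLibrary.from_tsv(path, sample_id=name)
        libs[name] = lib

        tags_tsv = out / f"{name}.tags.tsv"
        acct_json = out / f"{name}.accounting.json"
        bins_tsv = out / f"{name}.abundance_bins.tsv"
        stage(
            f"clean:{name}",
            [tags_tsv, acct_json, bins_tsv],
            lambda lib=lib, a=tags_tsv, b=acct_json, c=bins_tsv: (
                lib.to_tsv(a),
                lib.write_accounting_json(b),
                abundance_distribution(lib, tuple(config.params["bin_edges"]))
                .to_frame()
                .to_csv(c, sep="\t", index=False),
            ),
        )

        mapping = map_tags(lib, index, max_mismatch=config.params["max_mismatch"])
        gc = gene_counts(mapping, gene_ids=transcripts.gene_ids)
        counts[name] = gc
        status_tsv = out / f"{name}.tag_status.tsv"
        genes_tsv = out / f"{name}.gene_counts.tsv"
        summary_json = out / f"{name}.mapping_summary.json"

        def do_map(mapping=mapping, gc=gc, s=status_tsv, g=genes_tsv, j=summary_json):
            mapping.to_tsv(s)
            gc.to_tsv(g)
            summary = mapping.summary()
            summary["n_detected_genes"] = gc.n_detected_genes
            summary["pct_of_ref_genes"] = round(100.0 * gc.fraction_of_reference, 2)
            with open(j, "w") as fh:
                json.dump(summary, fh, indent=2)
                fh.write("\n")

        stage(f"map:{name}", [status_tsv, genes_tsv, summary_json], do_map)

        grid = config.params["saturation_grid"]
        if grid is None:
            total = lib.total_clean
            grid = sorted({max(1, int(total * f)) for f in
                           (0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)})
        grid = [g for g in grid if g <= lib.total_clean]
        sat_tsv = out / f"{name}.saturation.tsv"
        stage(
            f"saturation:{name}",
            [sat_tsv],
            lambda lib=lib, grid=grid, p=sat_tsv: saturation_curve(
                lib, index, grid, seed=config.seed,
                max_mismatch=config.params["max_mismatch"],
            ).to_tsv(p),
        )

    # -- dge -------------------------------------------------------------
    comparisons = [n for n in samples if n != control]
    de_tables: dict[str, pd.DataFrame] = {}
    up_sets: dict[str, list[str]] = {}
    down_sets: dict[str, list[str]] = {}
    for name in comparisons:
        de_tsv = out / f"de.{name}_vs_{control}.tsv"
        table = de_table(
            counts[control],
            counts[name],
            fdr_max=config.params["fdr_max"],
            min_abs_log2=config.params["min_abs_log2"],
            zero_floor=config.params["zero_floor"],
        )
        de_tables[name] = table
        up, down = call_degs(table, config.params["fdr_max"], config.params["min_abs_log2"])
        up_sets[name], down_sets[name] = up, down
        stage(
            f"dge:{name}",
            [de_tsv],
            lambda t=table, p=de_tsv: t.to_csv(p, sep="\t", index=False, float_format="%.6g"),
        )

    # -- enrich ----------------------------------------------------------
    if config.annotation is not None:
        if not config.annotation.exists():
            raise PipelineError(f"stage enrich: missing annotation {config.annotation}")
        annotation = read_annotation_tsv(config.annotation)
        for name in comparisons:
            enr_tsv = out / f"enrichment.{name}_vs_{control}.tsv"
            stage(
                f"enrich:{name}",
                [enr_tsv],
                lambda up=up_sets[name], p=enr_tsv: write_enrichment_tsv(
                    hypergeom_enrich(up, annotation, q_max=config.params["q_max"]), p
                ),
            )

    # -- report ----------------------------------------------------------
    report_path = out / "report.txt"
    stage(
        "report",
        [report_path],
        lambda: render_report(out, samples=list(samples), control=control, path=report_path),
    )
    manifest.save()
    return manifest.data


def render_report(outdir: Path, samples: list[str], control: str, path: Path) -> None:
    """Assemble the per-stage TSV/JSON outputs into one plain-text summary.

    Sections: library accounting, copy-number distribution, up/down DEG
    counts per comparison, enriched terms, and the most strongly induced
    genes with per-timepoint log2 ratios and significance flags.  A missing
    stage output drops its section with a warning instead of failing.
    """
    outdir = Path(outdir)
    lines: list[str] = ["# Tag library report", ""]

    lines.append("## Library accounting")
    header = ["metric", *samples]
    rows: dict[str, list] = {}
    ok = True
    for s in samples:
        j = outdir / f"{s}.mapping_summary.json"
        a = outdir / f"{s}.accounting.json"
        if not (j.exists() and a.exists()):
            log.warning("report: missing mapping/accounting for %s; section skipped", s)
            ok = False
            break
        with open(a) as fh:
            acct = json.load(fh)
        with open(j) as fh:
            summ = json.load(fh)
        for key in ("total_raw", "total_clean", "distinct_clean"):
            rows.setdefault(key, []).append(acct[key])
        for key in (
            "all_mapped_total", "all_mapped_total_pct",
            "unambiguous_total", "unambiguous_total_pct",
            "unknown_total", "unknown_total_pct",
            "n_detected_genes", "pct_of_ref_genes",
        ):
            rows.setdefault(key, []).append(summ[key])
    if ok:
        lines.append("\t".join(header))
        for key, vals in rows.items():
            lines.append("\t".join([key, *map(str, vals)]))
    lines.append("")

    lines.append("## Tag copy-number distribution")
    for s in samples:
        b = outdir / f"{s}.abundance_bins.tsv"
        if b.exists():
            lines.append(f"[{s}]")
            lines.append(b.read_text().rstrip())
        else:
            log.warning("report: missing abundance bins for %s", s)
    lines.append("")

    lines.append("## Differentially expressed genes (up / down)")
    ratio_cols: dict[str, pd.DataFrame] = {}
    for s in samples:
        if s == control:
            continue
        de = outdir / f"de.{s}_vs_{control}.tsv"
        if not de.exists():
            log.warning("report: missing DE table for %s", s)
            continue
        df = pd.read_csv(de, sep="\t")
        ratio_cols[s] = df
        sig = df[df["significant"]]
        n_up = int((sig["log2_ratio"] > 0).sum())
        n_down = int((sig["log2_ratio"] < 0).sum())
        lines.append(f"{s} vs {control}: up={n_up}\tdown={n_down}")
    lines.append("")

    lines.append("## Enriched terms (Q <= threshold flagged)")
    for s in samples:
        enr = outdir / f"enrichment.{s}_vs_{control}.tsv"
        if enr.exists():
            lines.append(f"[{s} vs {control}]")
            lines.append(enr.read_text().rstrip())
    lines.append("")

    if ratio_cols:
        lines.append("## Top induced genes (log2 ratio per comparison; * = significant)")
        merged: dict[str, dict[str, tuple[float, bool]]] = {}
        for s, df in ratio_cols.items():
            for _, row in df.iterrows():
                merged.setdefault(row["gene_id"], {})[s] = (
                    row["log2_ratio"], bool(row["significant"])
                )
        def best(entry):
            vals = [v for v, _ in entry.values() if pd.notna(v)]
            return max(vals) if vals else float("-inf")
        top = sorted(merged.items(), key=lambda kv: best(kv[1]), reverse=True)[:20]
        comp = [s for s in samples if s != control]
        lines.append("\t".join(["gene_id", *comp]))
        for gene, entry in top:
            cells = []
            for s in comp:
                if s in entry:
                    v, sig = entry[s]
                    cells.append(format_ratio(v) + ("*" if sig else ""))
                else:
                    cells.append("-")
            lines.append("\t".join([gene, *cells]))
        lines.append("")

    path.write_text("\n".join(lines) + "\n")
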