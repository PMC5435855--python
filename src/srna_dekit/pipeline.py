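"""End-to-end pipeline orchestration from a single JSON config.

Stage order: load reads -> filter -> align/annotate -> QC (raw) ->
normalization evaluation + chosen method -> QC (normalized) -> offset
estimation -> differential-expression call -> pattern clusters.  Every stage
writes plain-text outputs (TSV/JSON) into the run directory, a manifest
captures every parameter, and reruns with the same config and seed are
byte-identical.  With ``resume=True`` a stage whose outputs already exist is
reloaded instead of recomputed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .align import align_reads_exact
from .annotate import annotate_reads
from .core import (
    ConfigurationError,
    ExpressionMatrix,
    ReadLibrary,
    SampleHierarchy,
    build_expression_matrix,
    filter_matrix,
)
from .diffexpr import call_de, cluster_patterns
from .io import load_alignments, read_fasta_counts, read_matrix_tsv, write_matrix_tsv
from .normalization import evaluate_normalizations
from .offset import estimate_offset
from .qc import qc_report

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict = {
    "dialect": "count_suffix",
    "drop_replicates": [],
    "size_range": None,
    "annotation_types": ["miRNA", "siRNA", "tRNA", "rRNA", "snoRNA",
                         "protein_coding", "repeat"],
    "qc": {"top_n": 500, "abundance_window": 100.0},
    "normalization": {"methods": ["rpt", "tmm", "deseq", "quantile"],
                      "chosen": "tmm", "total_mode": "average"},
    "offset": {"window_len": 1000, "bias_bins": 100, "span": 0.3,
               "min_windows_per_level": 100, "fixed": None},
    "de": {"threshold": 1.0, "ci": "auto", "k": 2.0,
           "scheme": "consecutive", "reference": None,
           "min_size": 15, "drop_all_s": True},
    "seed": 0,
}


def _merge(defaults: dict, user: dict) -> dict:
    out = dict(defaults)
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


def _validate(config: dict) -> None:
    if "reads" not in config or "hierarchy" not in config:
        raise ConfigurationError("config must provide 'reads' and 'hierarchy'")
    for rid, path in config["reads"].items():
        if not Path(path).exists():
            raise ConfigurationError(f"reads file for {rid!r} not found: {path}")
    for key in ("genome", "gff", "alignments"):
        if config.get(key) and not Path(config[key]).exists():
            raise ConfigurationError(f"{key} file not found: {config[key]}")
    norm = config["normalization"]
    if len(norm["methods"]) > 6:
        raise ConfigurationError("at most six normalization methods may be evaluated")
    if norm["chosen"] not in norm["methods"]:
        raise ConfigurationError(
            f"chosen normalization {norm['chosen']!r} not in evaluated methods"
        )


def run_pipeline(config: dict, out_dir: str | Path, resume: bool = False) -> dict:
    """Execute the full pipeline; returns a summary dict of headline results."""
    config = _merge(DEFAULT_CONFIG, config)
    _validate(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log_handler = logging.FileHandler(out / "run.log", mode="a")
    log_handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("srna_dekit")
    root.addHandler(log_handler)
    try:
        return _run(config, out, resume)
    finally:
        root.removeHandler(log_handler)
        log_handler.close()


def _run(config: dict, out: Path, resume: bool) -> dict:
    hierarchy = SampleHierarchy.from_dict(
        json.load(open(config["hierarchy"]))
        if isinstance(config["hierarchy"], (str, Path))
        else config["hierarchy"]
    )

    # --- stage 1: load + collapse reads, build matrix
    matrix_path = out / "matrix_raw.tsv"
    libraries: dict[str, ReadLibrary] = {}
    if resume and matrix_path.exists():
        logger.info("resume: reloading %s", matrix_path)
        matrix = read_matrix_tsv(matrix_path, hierarchy)
        libraries = {rid: matrix.library(rid) for rid in matrix.replicate_ids}
    else:
        for rid, path in config["reads"].items():
            libraries[rid] = read_fasta_counts(path, config["dialect"], replicate_id=rid)
        matrix = build_expression_matrix(list(libraries.values()), hierarchy)
        write_matrix_tsv(matrix, matrix_path)

    # --- stage 2: filtering
    size_range = config["size_range"]
    matrix = filter_matrix(
        matrix,
        drop_replicates=config["drop_replicates"],
        size_range=tuple(size_range) if size_range else None,
    )
    hierarchy = matrix.hierarchy
    libraries = {rid: matrix.library(rid) for rid in matrix.replicate_ids}
    write_matrix_tsv(matrix, out / "matrix_filtered.tsv")

    # --- stage 3: alignment + annotation
    alignments = None
    classification = None
    if config.get("alignments"):
        union = ReadLibrary("union", _union_counts(libraries))
        alignments = load_alignments(config["alignments"], union)
    elif config.get("genome"):
        union = ReadLibrary("union", _union_counts(libraries))
        alignments = align_reads_exact(union, config["genome"])
    if alignments is not None and config.get("gff"):
        classification = annotate_reads(
            alignments, config["gff"], set(config["annotation_types"])
        )

    # --- stage 4: QC on raw data
    qc_cfg = config["qc"]
    report_raw = qc_report(matrix, alignments, classification,
                           top_n=qc_cfg["top_n"],
                           abundance_window=qc_cfg["abundance_window"])
    report_raw.write(out / "qc_raw")

    # --- stage 5: normalization evaluation + chosen method
    norm_cfg = config["normalization"]
    norm_path = out / "normalized.tsv"
    evaluation, ranking, results = evaluate_normalizations(
        matrix, norm_cfg["methods"], total_mode=norm_cfg["total_mode"],
        seed=config["seed"],
    )
    evaluation.to_csv(out / "evaluation.tsv", sep="\t", index=False, float_format="%.6g")
    ranking.to_csv(out / "ranking.tsv", sep="\t", index=False, float_format="%.6g")
    chosen = results[norm_cfg["chosen"]]
    if chosen.scale_factors:
        pd.Series(chosen.scale_factors, name="factor").to_csv(
            out / "factors.tsv", sep="\t", index_label="replicate", float_format="%.10g"
        )
    write_matrix_tsv(chosen.matrix, norm_path)

    # --- stage 6: QC on normalized data
    report_norm = qc_report(chosen.matrix, alignments, classification,
                            top_n=qc_cfg["top_n"],
                            abundance_window=qc_cfg["abundance_window"])
    report_norm.write(out / "qc_norm")

    # --- stage 7: offset estimation
    off_cfg = config["offset"]
    dataset_offset = off_cfg.get("fixed")
    offsets_path = out / "offsets.json"
    if dataset_offset is None and resume and offsets_path.exists():
        dataset_offset = json.load(open(offsets_path))["dataset_offset"]
    elif dataset_offset is None:
        if alignments is None:
            raise ConfigurationError(
                "offset estimation needs a genome or precomputed alignments; "
                "alternatively set offset.fixed in the config"
            )
        treatment_of = {rid: hierarchy.treatment_of(rid) for rid in hierarchy.replicate_ids}
        off = estimate_offset(
            alignments, libraries,
            window_len=off_cfg["window_len"],
            n_bias_bins=off_cfg["bias_bins"],
            min_windows_per_level=off_cfg["min_windows_per_level"],
            span=off_cfg["span"],
            treatment_of=treatment_of,
        )
        curves = pd.concat(
            [c.to_frame().assign(sample=sid) for sid, c in off.curves.items()],
            ignore_index=True,
        )[["sample", "abundance", "raw_kl", "smoothed_kl"]]
        curves.to_csv(out / "kl_curve.tsv", sep="\t", index=False, float_format="%.6g")
        with open(offsets_path, "w") as fh:
            json.dump({
                "sample_offsets": off.sample_offsets,
                "treatment_offsets": off.treatment_offsets,
                "dataset_offset": off.dataset_offset,
            }, fh, indent=2, sort_keys=True)
        dataset_offset = off.dataset_offset

    # --- stage 8: DE call + clustering
    de_cfg = config["de"]
    calls = call_de(
        chosen.matrix, offset=dataset_offset, threshold=de_cfg["threshold"],
        scheme=de_cfg["scheme"], reference=de_cfg["reference"],
        ci_method=de_cfg["ci"], k=de_cfg["k"],
    )
    calls.to_csv(out / "de_calls.tsv", sep="\t", index=False, float_format="%.6g")
    full, headline = cluster_patterns(calls, de_cfg["min_size"], de_cfg["drop_all_s"])
    with open(out / "clusters.tsv", "w") as fh:
        fh.write("pattern\tn\theadline\tsequences\n")
        for pat in sorted(full):
            seqs = full[pat]
            fh.write(f"{pat}\t{len(seqs)}\t{int(pat in headline)}\t{','.join(seqs)}\n")

    manifest = {
        "version": __version__,
        "config": _jsonable(config),
        "dataset_offset": dataset_offset,
        "n_sequences": len(matrix.sequences),
        "n_de": int(calls["de_flag"].sum()),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _union_counts(libraries: dict[str, ReadLibrary]) -> dict[str, int]:
    union: dict[str, int] = {}
    for lib in libraries.values():
        for seq, c in lib.counts.items():
            union[seq] = union.get(seq, 0) + c
    return union


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    return obj
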