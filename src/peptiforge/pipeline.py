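"""End-to-end screening pipeline: digest -> featurize -> predict -> screen.

The pipeline mirrors the discovery workflow: precursor proteins are
digested in silico with a chosen protease, the unique fragments are
scored by a trained activity classifier, and survivors of the screening
criteria are ranked by predicted probability.  Abundance and external
bioactivity score are peptidomics measurements, so when the input is a
digest (no such columns) only the length, position-2 and
model-probability criteria apply; when a candidate table with
``abundance`` and ``score`` columns is supplied, the full multi-criteria
filter runs.

A JSON report records counts at every stage, the seed and a config hash,
so identical inputs give identical reports (modulo timestamps, which are
deliberately omitted).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io
from .ml import TrainedModel, predict_candidates
from .proteolysis import DigestConfig, digest, get_rule
from .screening import ScreeningCriteria, apply_filters, position2_rule, rank_candidates


@dataclass
class PipelineConfig:
    """Structured configuration for :func:`run_pipeline`."""

    enzyme: str = "bromelain"
    missed_cleavages: int = 0
    min_length: int = 2
    algorithm: str = "lightgbm"
    seed: int = 0
    w: float = 0.05
    probability_threshold: float = 0.9
    max_length: int = 10
    min_abundance: float = 1e7
    min_score: float = 0.9
    outdir: str = "peptiforge_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def digest_config(self) -> DigestConfig:
        return DigestConfig(self.missed_cleavages, self.min_length)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


class PipelineError(RuntimeError):
    """A stage failure; the message names the failing stage."""


def run_pipeline(
    config: PipelineConfig,
    proteins,
    model: TrainedModel,
    candidate_table: pd.DataFrame | None = None,
    write_outputs: bool = True,
) -> dict:
    """Run the computational screening pipeline and return the report dict.

    ``proteins`` is a list of ``ProteinRecord``; ``model`` a trained
    activity classifier.  If ``candidate_table`` is given (columns
    ``sequence``, ``abundance``, ``score``), it is screened with the full
    criteria instead of the digest-derived peptides.
    """
    report: dict = {"config": asdict(config), "config_hash": config.hash(), "seed": config.seed, "stages": {}}
    outdir = Path(config.outdir)
    if write_outputs:
        outdir.mkdir(parents=True, exist_ok=True)

    try:
        rule = get_rule(config.enzyme)
        all_peptides = []
        for protein in proteins:
            all_peptides.extend(digest(protein, rule, config.digest_config()))
        report["stages"]["digest"] = {"proteins": len(proteins), "fragments": len(all_peptides)}
        if write_outputs:
            io.write_table(io.peptides_to_frame(all_peptides), outdir / "fragments.tsv")
    except Exception as exc:
        raise PipelineError(f"digest stage failed: {exc}") from exc

    try:
        if candidate_table is not None:
            candidates = candidate_table.copy()
        else:
            candidates = pd.DataFrame({"sequence": sorted({p.sequence for p in all_peptides})})
        preds = predict_candidates(model, candidates["sequence"], threshold=config.probability_threshold)
        candidates = candidates.merge(preds, on="sequence", how="inner")
        report["stages"]["predict"] = {
            "candidates": len(candidates),
            "high_confidence": int(candidates["high_confidence"].sum()),
        }
        if write_outputs:
            io.write_table(candidates, outdir / "predictions.csv")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"predict stage failed: {exc}") from exc

    try:
        criteria = ScreeningCriteria(config.min_abundance, config.max_length, config.min_score)
        if {"abundance", "score"} <= set(candidates.columns):
            screened, rejections = apply_filters(candidates, criteria)
            screened = screened[screened["high_confidence"]]
            report["stages"]["screen"] = {"mode": "full", "rejections": rejections}
        else:
            mask = (
                (candidates["sequence"].str.len() < criteria.max_length)
                & candidates["sequence"].map(lambda s: position2_rule(s, criteria.position2_residues))
                & candidates["high_confidence"]
            )
            screened = candidates[mask]
            report["stages"]["screen"] = {"mode": "digest-only (no abundance/score columns)"}
        ranked = rank_candidates(screened, ["probability"], descending=True)
        report["stages"]["screen"]["survivors"] = len(ranked)
        if write_outputs:
            io.write_table(ranked, outdir / "survivors.csv")
            io.write_json_report(report, outdir / "report.json")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"screen stage failed: {exc}") from exc

    counts = [
        report["stages"]["digest"]["fragments"],
        report["stages"]["predict"]["candidates"],
        report["stages"]["screen"]["survivors"],
    ]
    report["counts_non_increasing"] = all(a >= b for a, b in zip(counts, counts[1:])) if candidate_table is None else None
    return report
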