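"""Confidence scoring for protein-function annotations from heterogeneous evidence.

Experimental support for an enzyme's proposed function comes in very different
shapes: kcat/Km measurements, relative-activity substrate screens, qualitative
gel/HPLC/X-ray observations, and genetic knockout or complementation phenotypes.
This module maps each evidence record to a score in [0, 1], combines the genetic
and biochemical categories with a noisy-OR, and then adjusts each annotation's
score against the distribution of scores for the same protein, so that a single
strongly supported function among many weakly supported ones is boosted.

The scale is anchored at round kcat/Km values (10^3..10^7 M^-1 s^-1); values in
between are interpolated linearly in log10. All constants live in
:class:`ScoreTable` and can be overridden from a YAML file.
"""

from __future__ import annotations

import logging
import math
import sys
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

GENETIC = "genetic"
BIOCHEMICAL = "biochemical"
CATEGORIES = (GENETIC, BIOCHEMICAL)

GENETIC_SUBTYPES = frozenset(
    {"knockout_predicted", "knockout_related", "knockout_inexplicable", "rescue"}
)
VALUE_SUBTYPES = frozenset({"kcat_km", "pseudo_kcat_km", "relative_activity"})
QUALITATIVE_SUBTYPES = frozenset(
    {"gel_rare_substrate", "gel_hplc_common", "xray_binding", "xray_substrate",
     "positive_activity"}
)
SUBTYPES = GENETIC_SUBTYPES | VALUE_SUBTYPES | QUALITATIVE_SUBTYPES


@dataclass(frozen=True)
class EvidenceRecord:
    """One experimental observation tied to a (protein, function) pair.

    ``value`` is required exactly for the quantitative subtypes (kcat_km,
    pseudo_kcat_km in M^-1 s^-1; relative_activity in percent) and must be
    absent otherwise. Relative activities above 100% (a screen whose best
    substrate was redefined midway) are clamped to 100 with a warning.
    """

    protein_id: str
    function_id: str
    category: str
    subtype: str
    value: float | None = None
    source_ref: str = ""

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.subtype not in SUBTYPES:
            raise ValueError(f"unknown subtype {self.subtype!r}")
        expected = GENETIC if self.subtype in GENETIC_SUBTYPES else BIOCHEMICAL
        if self.category != expected:
            raise ValueError(
                f"subtype {self.subtype!r} belongs to category {expected!r}, "
                f"got {self.category!r}"
            )
        if self.subtype in VALUE_SUBTYPES:
            if self.value is None:
                raise ValueError(f"subtype {self.subtype!r} requires a value")
            if self.value < 0:
                raise ValueError(f"negative value for {self.subtype!r}")
            if self.subtype == "relative_activity" and self.value > 100:
                logger.warning(
                    "relative activity %.4g%% for %s/%s clamped to 100",
                    self.value, self.protein_id, self.function_id,
                )
                object.__setattr__(self, "value", 100.0)
        elif self.value is not None:
            raise ValueError(f"subtype {self.subtype!r} must not carry a value")


@dataclass(frozen=True)
class ScoreTable:
    """All per-evidence scoring constants.

    Anchor maps are keyed by log10(kcat/Km); scores must be in [0, 1] and
    strictly increasing with the anchor value. ``*_zero_score`` is the score
    for a reported activity of exactly zero.
    """

    kinetic_anchors: Mapping[float, float] = field(
        default_factory=lambda: {3: 0.1, 4: 0.2, 5: 0.5, 6: 0.85, 7: 0.99}
    )
    kinetic_zero_score: float = 0.01
    pseudo_anchors: Mapping[float, float] = field(
        default_factory=lambda: {3: 0.05, 4: 0.1, 5: 0.25, 6: 0.5, 7: 0.7}
    )
    pseudo_zero_score: float = 0.01
    genetic_scores: Mapping[str, float] = field(
        default_factory=lambda: {
            "knockout_predicted": 0.99,
            "knockout_related": 0.7,
            "knockout_inexplicable": 0.1,
            "rescue": 0.5,
        }
    )
    qualitative_scores: Mapping[str, float] = field(
        default_factory=lambda: {
            "gel_rare_substrate": 0.5,
            "gel_hplc_common": 0.05,
            "xray_binding": 0.5,
            "xray_substrate": 0.01,
            "positive_activity": 0.01,
        }
    )
    relative_activity_max_score: float = 0.1
    population_sd: bool = True

    def __post_init__(self) -> None:
        for anchors in (self.kinetic_anchors, self.pseudo_anchors):
            keys = sorted(anchors)
            scores = [anchors[k] for k in keys]
            if any(not 0 <= s <= 1 for s in scores):
                raise ValueError("anchor scores must lie in [0, 1]")
            if any(b <= a for a, b in zip(scores, scores[1:])):
                raise ValueError("anchor scores must increase strictly with log10 value")
        for m in (self.genetic_scores, self.qualitative_scores):
            if any(not 0 <= s <= 1 for s in m.values()):
                raise ValueError("scores must lie in [0, 1]")
        if not 0 <= self.relative_activity_max_score <= 1:
            raise ValueError("relative_activity_max_score must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str) -> "ScoreTable":
        """Load overrides from a YAML file; keys mirror the dataclass fields."""
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("kinetic_anchors", "pseudo_anchors"):
            if key in raw:
                raw[key] = {float(k): float(v) for k, v in raw[key].items()}
        for key, value in raw.items():
            logger.info("score table override: %s = %r", key, value)
        return replace(cls(), **raw)


@dataclass(frozen=True)
class ScoredAnnotation:
    """A (protein, function) pair with category, combined and adjusted scores."""

    protein_id: str
    function_id: str
    s_genetic: float
    s_biochem: float
    s_overall: float
    z_score: float
    s_final: float
    n_records: int


def _interp_log(value: float, anchors: Mapping[float, float], zero_score: float) -> float:
    """Piecewise-linear interpolation in log10(value) over anchor points.

    Values above the top anchor clamp to the top score; nonzero values below
    the bottom anchor clamp to the bottom score (only value == 0 maps to the
    dedicated zero-activity score).
    """
    if value < 0:
        raise ValueError("kinetic value must be non-negative")
    if value == 0:
        return zero_score
    lv = math.log10(value)
    keys = sorted(anchors)
    if lv <= keys[0]:
        return anchors[keys[0]]
    if lv >= keys[-1]:
        return anchors[keys[-1]]
    for lo, hi in zip(keys, keys[1:]):
        if lv <= hi:
            frac = (lv - lo) / (hi - lo)
            return anchors[lo] + frac * (anchors[hi] - anchors[lo])
    raise AssertionError("unreachable")


def score_kinetic(value: float, table: ScoreTable | None = None) -> float:
    """Score a kcat/Km measurement (M^-1 s^-1) on the anchored log10 scale."""
    table = table or ScoreTable()
    return _interp_log(value, table.kinetic_anchors, table.kinetic_zero_score)


def score_pseudo_kinetic(value: float, table: ScoreTable | None = None) -> float:
    """Score a pseudo-kcat/Km estimate; same interpolation, lower anchors."""
    table = table or ScoreTable()
    return _interp_log(value, table.pseudo_anchors, table.pseudo_zero_score)


def pseudo_kcat_km(rel_a: float, rel_b: float, kcat_km_b: float) -> float:
    """Estimate kcat/Km for substrate A from a relative-activity screen.

    Substrate B has a measured kcat/Km; A's estimate scales it by the squared
    ratio of relative activities, reflecting the assumption that catalytic
    efficiency changes faster than linearly with screened activity.
    """
    if rel_b <= 0:
        raise ValueError("reference relative activity must be positive")
    if rel_a < 0 or kcat_km_b < 0:
        raise ValueError("relative activity and kcat/Km must be non-negative")
    return (rel_a / rel_b) ** 2 * kcat_km_b


def score_relative_activity(rel: float, table: ScoreTable | None = None) -> float:
    """Score a bare relative activity: linear from 0 (0%) to the cap (100%)."""
    table = table or ScoreTable()
    if rel < 0:
        raise ValueError("relative activity must be non-negative")
    if rel > 100:
        logger.warning("relative activity %.4g%% clamped to 100", rel)
        rel = 100.0
    return table.relative_activity_max_score * rel / 100.0


def score_record(record: EvidenceRecord, table: ScoreTable | None = None) -> float:
    """Dispatch one evidence record to the appropriate scorer."""
    table = table or ScoreTable()
    if record.subtype in GENETIC_SUBTYPES:
        return table.genetic_scores[record.subtype]
    if record.subtype in QUALITATIVE_SUBTYPES:
        return table.qualitative_scores[record.subtype]
    assert record.value is not None
    if record.subtype == "kcat_km":
        return score_kinetic(record.value, table)
    if record.subtype == "pseudo_kcat_km":
        return score_pseudo_kinetic(record.value, table)
    return score_relative_activity(record.value, table)


def score_category(records: Sequence[EvidenceRecord],
                   table: ScoreTable | None = None) -> float:
    """Score one evidence category for one annotation: the max over records."""
    if not records:
        raise ValueError("empty record list; an absent category scores 0 upstream")
    categories = {r.category for r in records}
    if len(categories) > 1:
        raise ValueError(f"mixed categories in one call: {sorted(categories)}")
    table = table or ScoreTable()
    return max(score_record(r, table) for r in records)


def combine_overall(s_genetic: float, s_biochem: float) -> float:
    """Noisy-OR combination of the two category scores.

    S_overall = 1 - (1 - S_genetic)(1 - S_biochem): independent lines of
    evidence reinforce each other, and a missing category (score 0) passes
    the other through unchanged.
    """
    if not (0 <= s_genetic <= 1 and 0 <= s_biochem <= 1):
        raise ValueError("category scores must lie in [0, 1]")
    return 1.0 - (1.0 - s_genetic) * (1.0 - s_biochem)


def adjust_final(overall_scores: Sequence[float],
                 population_sd: bool = True) -> tuple[list[float], list[float]]:
    """Z-score adjustment of all of one protein's overall scores.

    Each score's Z against the protein's own score distribution determines the
    adjustment: an outlier above the mean is pushed toward 1
    (S_final = 1 - (1 - S)/(1 + |Z|)), one below the mean toward 0
    (S_final = S/(1 + |Z|)), and Z = 0 passes through. If the SD is zero
    (identical scores, or a single annotation) all Z are defined as 0.

    Returns (z_scores, final_scores), index-aligned with the input.
    """
    if not overall_scores:
        raise ValueError("empty score list")
    n = len(overall_scores)
    mean = sum(overall_scores) / n
    var = sum((s - mean) ** 2 for s in overall_scores)
    var /= n if population_sd else max(n - 1, 1)
    sd = math.sqrt(var)
    z_scores: list[float] = []
    finals: list[float] = []
    for s in overall_scores:
        z = 0.0 if sd == 0 else (s - mean) / sd
        if z > 0:
            f = 1.0 - (1.0 - s) / (1.0 + abs(z))
        elif z < 0:
            f = s / (1.0 + abs(z))
        else:
            f = s
        z_scores.append(z)
        finals.append(f)
    return z_scores, finals


def score_dataset(records: Iterable[EvidenceRecord],
                  table: ScoreTable | None = None) -> list[ScoredAnnotation]:
    """Score a full evidence table: one annotation per (protein, function) pair.

    Per pair, each category is scored by its max record and the two categories
    are combined; per protein, all pairs are then Z-adjusted together. Output
    is sorted lexicographically by (protein_id, function_id) and is invariant
    under permutation of the input records.
    """
    table = table or ScoreTable()
    grouped: dict[tuple[str, str], list[EvidenceRecord]] = {}
    for rec in records:
        grouped.setdefault((rec.protein_id, rec.function_id), []).append(rec)

    per_protein: dict[str, list[tuple[str, float, float, float, int]]] = {}
    for (protein, function) in sorted(grouped):
        recs = grouped[(protein, function)]
        genetic = [r for r in recs if r.category == GENETIC]
        biochem = [r for r in recs if r.category == BIOCHEMICAL]
        s_gen = score_category(genetic, table) if genetic else 0.0
        s_bio = score_category(biochem, table) if biochem else 0.0
        s_all = combine_overall(s_gen, s_bio)
        per_protein.setdefault(protein, []).append(
            (function, s_gen, s_bio, s_all, len(recs))
        )

    out: list[ScoredAnnotation] = []
    for protein in sorted(per_protein):
        rows = per_protein[protein]
        zs, finals = adjust_final([r[3] for r in rows], table.population_sd)
        for (function, s_gen, s_bio, s_all, n), z, f in zip(rows, zs, finals):
            out.append(ScoredAnnotation(protein, function, s_gen, s_bio, s_all, z, f, n))
    return out


# --- tabular I/O -----------------------------------------------------------

EVIDENCE_COLUMNS = ["protein_id", "function_id", "category", "subtype", "value",
                    "source_ref"]
SCORE_COLUMNS = ["protein_id", "function_id", "s_genetic", "s_biochem",
                 "s_overall", "z_score", "s_final", "n_records"]


def read_evidence_tsv(path: str) -> list[EvidenceRecord]:
    """Read an evidence TSV; malformed rows are logged with their row number
    and skipped."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(EVIDENCE_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise ValueError(f"evidence table missing columns: {sorted(missing)}")
    records: list[EvidenceRecord] = []
    for idx, row in df.iterrows():
        try:
            raw_value = row.get("value", "")
            value = float(raw_value) if str(raw_value).strip() != "" else None
            records.append(EvidenceRecord(
                protein_id=row["protein_id"],
                function_id=row["function_id"],
                category=row["category"],
                subtype=row["subtype"],
                value=value,
                source_ref=row.get("source_ref", ""),
            ))
        except (ValueError, KeyError) as exc:
            logger.error("skipping evidence row %d: %s", int(idx) + 2, exc)
    return records


def annotations_to_frame(annotations: Sequence[ScoredAnnotation]) -> pd.DataFrame:
    return pd.DataFrame([a.__dict__ for a in annotations], columns=SCORE_COLUMNS)


def write_scores_tsv(annotations: Sequence[ScoredAnnotation], path: str) -> None:
    """Write scored annotations as TSV with scores printed to 4 decimals."""
    df = annotations_to_frame(annotations)
    for col in ("s_genetic", "s_biochem", "s_overall", "z_score", "s_final"):
        df[col] = df[col].map(lambda x: f"{x:.4f}")
    df.to_csv(path, sep="\t", index=False)


def _configure_stderr_logging() -> None:
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        logger.addHandler(handler)
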