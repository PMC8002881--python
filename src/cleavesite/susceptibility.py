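"""Amino-acid-composition and cleavage-site susceptibility scores.

Per-protein percentages quantifying vulnerability to three proteolysis
mechanisms:

* UV susceptibility: UV-chromophore residues (Trp, Tyr, and half the
  count of disulfide-bonded cysteines, i.e. the cystine count) per
  residue, times 100.
* ROS susceptibility: oxidation-sensitive residues (Trp, Tyr, Met, Cys,
  His) per residue, times 100.
* Combined UV-ROS susceptibility: both sets together; note that
  disulfide-bonded cysteines contribute twice (once in the Cys term, once
  as half a cystine), which is the published formula taken literally; set
  ``double_count_cystine=False`` for the non-double-counting variant.
* Protease susceptibility: high-confidence predicted cleavage sites
  (ensemble score strictly above a threshold, default 0.8) per residue,
  times 100.

Classification: a protein is called UV-susceptible when its UV score
exceeds 5% and ROS-susceptible when its ROS score exceeds 10% (strict
inequalities; thresholds configurable).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import CleavageAnnotation, ProteinRecord, ValidationError

UV_THRESHOLD = 5.0
ROS_THRESHOLD = 10.0
SCORE_THRESHOLD = 0.8


@dataclass(frozen=True)
class CompositionProfile:
    """Counts of the photo/oxidation-labile residues of one protein."""

    trp: int
    tyr: int
    met: int
    cys: int
    his: int
    n_bonded_cys: int
    length: int

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValidationError("length must be >= 1")
        if self.n_bonded_cys > self.cys:
            raise ValidationError("more disulfide-bonded Cys than Cys residues")
        if self.n_bonded_cys % 2:
            raise ValidationError("n_bonded_cys must be even (2 per bond)")

    @classmethod
    def from_protein(cls, protein: ProteinRecord) -> "CompositionProfile":
        seq = protein.sequence
        return cls(
            trp=seq.count("W"),
            tyr=seq.count("Y"),
            met=seq.count("M"),
            cys=seq.count("C"),
            his=seq.count("H"),
            n_bonded_cys=2 * len(protein.disulfide_pairs),
            length=protein.length,
        )


def uv_susceptibility(protein: ProteinRecord) -> float:
    """(Trp + Tyr + cystine) / length * 100, cystine = bonded Cys / 2."""
    p = CompositionProfile.from_protein(protein)
    return (p.trp + p.tyr + p.n_bonded_cys / 2.0) / p.length * 100.0


def ros_susceptibility(protein: ProteinRecord) -> float:
    """(Trp + Tyr + Met + Cys + His) / length * 100 (all Cys count)."""
    p = CompositionProfile.from_protein(protein)
    return (p.trp + p.tyr + p.met + p.cys + p.his) / p.length * 100.0


def uv_ros_susceptibility(protein: ProteinRecord, double_count_cystine: bool = True) -> float:
    """Combined score; bonded Cys appear in both the Cys and cystine terms.

    With ``double_count_cystine=False`` bonded cysteines are counted only
    once (in the Cys term) and the score equals the ROS score.
    """
    p = CompositionProfile.from_protein(protein)
    cystine_term = p.n_bonded_cys / 2.0 if double_count_cystine else 0.0
    return (p.trp + p.tyr + p.met + p.cys + p.his + cystine_term) / p.length * 100.0


def protease_susceptibility(
    protein: ProteinRecord,
    predictions: Iterable[CleavageAnnotation],
    threshold: float = SCORE_THRESHOLD,
) -> float:
    """High-confidence predicted sites per residue, as a percentage.

    Counts predictions for this protein whose score is strictly above
    ``threshold`` (default 0.8, the high-confidence cut) and divides by
    protein length.
    """
    if not (0.0 < threshold < 1.0):
        raise ValidationError("threshold must lie in (0, 1)")
    n = sum(
        1
        for a in predictions
        if a.protein_id == protein.id and a.score is not None and a.score > threshold
    )
    return n / protein.length * 100.0


def classify_uv_ros(
    uv: float,
    ros: float,
    uv_threshold: float = UV_THRESHOLD,
    ros_threshold: float = ROS_THRESHOLD,
) -> tuple[str, str]:
    """Threshold the composition scores into susceptible/resistant calls.

    Strictly greater than 5% UV-chromophore content flags UV
    susceptibility; strictly greater than 10% oxidation-sensitive content
    flags ROS susceptibility.
    """
    uv_class = "susceptible" if uv > uv_threshold else "resistant"
    ros_class = "susceptible" if ros > ros_threshold else "resistant"
    return uv_class, ros_class


@dataclass(frozen=True)
class SusceptibilityScores:
    """All susceptibility scores of one protein."""

    protein_id: str
    uv: float
    ros: float
    uv_ros: float
    protease_scores: Mapping[str, float]
    uv_class: str
    ros_class: str
    threshold: float = SCORE_THRESHOLD


def score_protein(
    protein: ProteinRecord,
    predictions_by_protease: Mapping[str, Iterable[CleavageAnnotation]] | None = None,
    threshold: float = SCORE_THRESHOLD,
    uv_threshold: float = UV_THRESHOLD,
    ros_threshold: float = ROS_THRESHOLD,
    double_count_cystine: bool = True,
) -> SusceptibilityScores:
    uv = uv_susceptibility(protein)
    ros = ros_susceptibility(protein)
    uv_ros = uv_ros_susceptibility(protein, double_count_cystine)
    protease_scores = {
        protease: protease_susceptibility(protein, preds, threshold)
        for protease, preds in (predictions_by_protease or {}).items()
    }
    uv_class, ros_class = classify_uv_ros(uv, ros, uv_threshold, ros_threshold)
    return SusceptibilityScores(
        protein_id=protein.id,
        uv=uv,
        ros=ros,
        uv_ros=uv_ros,
        protease_scores=protease_scores,
        uv_class=uv_class,
        ros_class=ros_class,
        threshold=threshold,
    )


def proteome_report(
    proteins: Sequence[ProteinRecord],
    predictions_by_protease: Mapping[str, Iterable[CleavageAnnotation]] | None = None,
    threshold: float = SCORE_THRESHOLD,
    uv_threshold: float = UV_THRESHOLD,
    ros_threshold: float = ROS_THRESHOLD,
    double_count_cystine: bool = True,
) -> pd.DataFrame:
    """One row per protein with composition and protease scores.

    ``predictions_by_protease`` maps protease id to scored cleavage
    annotations (any protein).  Rows are ordered by descending combined
    UV-ROS score, ties broken by protein id.
    """
    if not proteins:
        raise ValidationError("proteome_report needs at least one protein")
    preds = {
        protease: list(annots) for protease, annots in (predictions_by_protease or {}).items()
    }
    rows = []
    for protein in proteins:
        s = score_protein(
            protein, preds, threshold, uv_threshold, ros_threshold, double_count_cystine
        )
        row = {
            "protein_id": protein.id,
            "length": protein.length,
            "uv": s.uv,
            "ros": s.ros,
            "uv_ros": s.uv_ros,
            "uv_class": s.uv_class,
            "ros_class": s.ros_class,
        }
        for protease, val in s.protease_scores.items():
            row[f"protease_{protease}"] = val
        rows.append(row)
    df = pd.DataFrame(rows)
    df = df.sort_values(
        ["uv_ros", "protein_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return df


def compare_susceptibility_groups(
    report: pd.DataFrame,
    group_a_ids: Iterable[str],
    group_b_ids: Iterable[str],
    column: str,
) -> tuple[float, float]:
    """Student's t-test on a report column between two protein groups.

    Used for e.g. the cleaved-vs-uncleaved comparison: do proteins with
    experimentally observed cleavage have higher predicted protease
    susceptibility than those without?
    """
    from .evaluation import compare_groups

    a = report.loc[report["protein_id"].isin(set(group_a_ids)), column].to_numpy()
    b = report.loc[report["protein_id"].isin(set(group_b_ids)), column].to_numpy()
    return compare_groups(a, b)
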