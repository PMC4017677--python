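"""Protein-evidence handling: ordinal levels -> per-reaction scores.

Immunohistochemistry annotation yields an ordinal detection level per gene
per sample: strong / moderate / weak / negative, with some proteins simply
not measured in a given sample.  Reconstruction needs one real-valued score
per reaction of the reference network, so this module provides the three
steps in between:

1. :func:`impute_missing` — fill a sample's unmeasured genes with the
   cohort median of the other samples (on the ordinal 0–3 scale).
2. :func:`gene_scores` — map levels to numeric scores.  Detected levels
   (weak and up) map to positive scores, absence to negative ones, so the
   selection MILP is rewarded for keeping reactions with detected enzymes
   and penalised for keeping undetected ones.
3. :func:`reaction_scores` — aggregate gene scores through each reaction's
   GPR rule (OR = max across isozymes, AND = min across complex subunits).

The ordinal median uses a fixed tie rule for even cohorts: the midpoint when
it is integral, otherwise rounded down.  Median of {strong, weak} = moderate;
median of {strong, moderate} = moderate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .gem_core import Model

__all__ = [
    "LEVEL_CODES",
    "CODE_LEVELS",
    "DEFAULT_SCORE_MAPPING",
    "EvidenceMatrix",
    "ScoreVector",
    "ordinal_median",
    "impute_missing",
    "gene_scores",
    "reaction_scores",
    "read_score_mapping",
]

LEVEL_CODES: Dict[str, int] = {"negative": 0, "weak": 1, "moderate": 2, "strong": 3}
CODE_LEVELS: Dict[int, str] = {v: k for k, v in LEVEL_CODES.items()}

#: Default level -> score table.  High positive for strong detection, mild
#: negative for measured absence, weakly negative for never-measured genes;
#: fully configurable.
DEFAULT_SCORE_MAPPING: Dict[str, float] = {
    "strong": 20.0,
    "moderate": 15.0,
    "weak": 10.0,
    "negative": -8.0,
    "missing": -2.0,
}

#: Per-reaction score map (reaction id -> weight for the selection MILP).
ScoreVector = Dict[str, float]


@dataclass
class EvidenceMatrix:
    """Ordinal protein-evidence levels, genes x samples.

    Stored as a float DataFrame with codes 0–3 and NaN for missing; the
    string levels appear only at the TSV boundary.
    """

    data: pd.DataFrame  # index: gene ids; columns: sample ids; values 0-3/NaN

    def __post_init__(self) -> None:
        values = self.data.to_numpy(dtype=float)
        valid = np.isnan(values) | np.isin(values, list(CODE_LEVELS))
        if not valid.all():
            raise ValueError("evidence levels must be in {0,1,2,3} or NaN")
        if self.data.index.has_duplicates or self.data.columns.has_duplicates:
            raise ValueError("duplicate gene or sample ids in evidence matrix")

    @property
    def genes(self) -> List[str]:
        return list(self.data.index)

    @property
    def samples(self) -> List[str]:
        return list(self.data.columns)

    def level(self, gene: str, sample: str) -> Optional[str]:
        v = self.data.at[gene, sample]
        return None if pd.isna(v) else CODE_LEVELS[int(v)]

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_levels(
        cls, levels: Mapping[str, Mapping[str, Optional[str]]]
    ) -> "EvidenceMatrix":
        """Build from nested dict gene -> sample -> level name (None=missing)."""
        frame = pd.DataFrame(
            {
                g: {s: (np.nan if lv is None else float(LEVEL_CODES[lv]))
                    for s, lv in row.items()}
                for g, row in levels.items()
            }
        ).T
        return cls(frame)

    @classmethod
    def read_tsv(cls, path: str) -> "EvidenceMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                            keep_default_na=False)
        def _decode(cell: str) -> float:
            cell = cell.strip()
            if cell in ("", "NA", "na", "NaN"):
                return np.nan
            if cell not in LEVEL_CODES:
                raise ValueError(f"unknown evidence level {cell!r}")
            return float(LEVEL_CODES[cell])
        return cls(frame.map(_decode))

    def to_tsv(self, path: str) -> None:
        out = self.data.map(
            lambda v: "NA" if pd.isna(v) else CODE_LEVELS[int(v)]
        )
        out.index.name = "gene"
        out.to_csv(path, sep="\t")


def ordinal_median(values: Sequence[float]) -> int:
    """Median on the ordinal scale with the fixed even-cohort tie rule.

    Odd counts give the middle element.  Even counts give the midpoint of
    the two middle elements when that is integral, else the midpoint rounded
    down (median of codes {3, 2} -> 2).
    """
    if len(values) == 0:
        raise ValueError("median of empty cohort")
    return int(math.floor(float(np.median(np.asarray(values, dtype=float))) + 1e-9))


def impute_missing(matrix: EvidenceMatrix, sample: str) -> EvidenceMatrix:
    """Fill a sample's missing genes with the cohort median of other samples.

    Only (gene, ``sample``) cells that are missing change; measured values
    are never altered, and genes missing in every other sample stay missing.
    Re-running on the result is a no-op for genes that were filled.
    """
    if sample not in matrix.samples:
        raise KeyError(f"unknown sample {sample!r}")
    others = [s for s in matrix.samples if s != sample]
    if not others:
        raise ValueError("cannot impute from a single-sample matrix (no cohort)")
    frame = matrix.data.copy()
    target = frame[sample]
    for gene in frame.index[target.isna()]:
        cohort = frame.loc[gene, others].dropna()
        if len(cohort):
            frame.at[gene, sample] = float(ordinal_median(cohort.to_numpy()))
    return EvidenceMatrix(frame)


def gene_scores(
    matrix: EvidenceMatrix,
    sample: str,
    mapping: Optional[Mapping[str, float]] = None,
) -> Dict[str, float]:
    """Numeric score per gene for one sample under a level->score table.

    ``mapping`` must define all five symbols (strong, moderate, weak,
    negative, missing); genes still missing after imputation get the
    ``missing`` score.
    """
    mapping = dict(DEFAULT_SCORE_MAPPING if mapping is None else mapping)
    needed = set(DEFAULT_SCORE_MAPPING)
    if set(mapping) < needed:
        raise ValueError(
            f"score mapping must define {sorted(needed)}; "
            f"missing {sorted(needed - set(mapping))}"
        )
    if sample not in matrix.samples:
        raise KeyError(f"unknown sample {sample!r}")
    column = matrix.data[sample]
    out: Dict[str, float] = {}
    for gene, v in column.items():
        out[gene] = mapping["missing"] if pd.isna(v) else mapping[CODE_LEVELS[int(v)]]
    return out


def reaction_scores(
    model: Model,
    gene_score_map: Mapping[str, float],
    spontaneous_score: float = 0.0,
    missing_score: Optional[float] = None,
) -> ScoreVector:
    """Aggregate gene scores through GPR rules into per-reaction weights.

    OR nodes take the maximum child score (any isozyme suffices), AND nodes
    the minimum (every subunit needed).  Reactions without a gene rule get
    ``spontaneous_score``; genes absent from ``gene_score_map`` get
    ``missing_score`` (default: the standard missing-evidence score).
    """
    if missing_score is None:
        missing_score = DEFAULT_SCORE_MAPPING["missing"]
    scores: ScoreVector = {}
    for rxn in model.reactions:
        if rxn.gene_rule is None:
            scores[rxn.id] = float(spontaneous_score)
        else:
            scores[rxn.id] = rxn.gene_rule.evaluate(gene_score_map,
                                                    missing=missing_score)
    return scores


def read_score_mapping(path: str) -> Dict[str, float]:
    """Read a ``level=score`` override file (one pair per line, # comments)."""
    mapping = dict(DEFAULT_SCORE_MAPPING)
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed score-mapping line {line!r}")
            key, val = (p.strip() for p in line.split("=", 1))
            if key not in DEFAULT_SCORE_MAPPING:
                raise ValueError(f"unknown evidence level {key!r}")
            mapping[key] = float(val)
    return mapping
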