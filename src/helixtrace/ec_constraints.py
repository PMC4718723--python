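"""Evolutionary-coupling contact constraints: I/O, filtering, model scoring.

A coupling analysis of a protein family yields residue pairs whose
co-variation predicts spatial proximity.  Here those pairs are the currency
for validating (and searching) backbone models: the headline statistic is
the fraction of the top-N pairs whose Cα–Cα distance in a model falls under
a threshold (15 Å by default), together with the mean pair distance.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .helix_geometry import BackboneModel

__all__ = [
    "ContactPair",
    "SatisfactionReport",
    "read_contacts",
    "write_contacts",
    "top_n",
    "satisfaction",
]

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 15.0   # Å, model-checking distance for a satisfied pair
DEFAULT_TOP_INTRA = 90     # top couplings used within the traced chain
DEFAULT_TOP_INTER = 6      # top couplings to the partner ring
DEFAULT_MIN_SEPARATION = 5


@dataclass(frozen=True)
class ContactPair:
    """One co-evolving residue pair (1-based indices, unitless score)."""

    res_i: int
    res_j: int
    score: float
    chain_i: str = "A"
    chain_j: str = "A"

    def __post_init__(self) -> None:
        if self.chain_i == self.chain_j and self.res_i == self.res_j:
            raise ValueError("same-chain pair must couple two distinct residues")
        if not np.isfinite(self.score):
            raise ValueError("score must be finite")

    @property
    def same_chain(self) -> bool:
        return self.chain_i == self.chain_j

    @property
    def separation(self) -> int:
        return abs(self.res_i - self.res_j)


@dataclass
class SatisfactionReport:
    """Constraint-satisfaction summary of a pair list against a model.

    ``fraction_satisfied`` and ``mean_distance`` are computed over resolvable
    pairs only; pairs whose residues are absent from the model are listed in
    ``unresolved`` and never silently dropped or counted as violations.
    """

    n_pairs: int
    n_satisfied: int
    threshold: float
    mean_distance: float
    violations: list = field(default_factory=list)
    unresolved: list = field(default_factory=list)

    @property
    def fraction_satisfied(self) -> float:
        return self.n_satisfied / self.n_pairs

    def to_dict(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "n_satisfied": self.n_satisfied,
            "fraction_satisfied": self.fraction_satisfied,
            "mean_distance": self.mean_distance,
            "threshold": self.threshold,
            "violations": [
                {"res_i": p.res_i, "res_j": p.res_j, "chain_i": p.chain_i,
                 "chain_j": p.chain_j, "distance": d}
                for p, d in self.violations
            ],
            "unresolved": [
                {"res_i": p.res_i, "res_j": p.res_j,
                 "chain_i": p.chain_i, "chain_j": p.chain_j}
                for p in self.unresolved
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def to_table(self) -> str:
        lines = [
            f"pairs          {self.n_pairs}",
            f"satisfied      {self.n_satisfied}  ({100 * self.fraction_satisfied:.1f}% at {self.threshold:g} A)",
            f"mean distance  {self.mean_distance:.2f} A",
            f"violations     {len(self.violations)}",
            f"unresolved     {len(self.unresolved)}",
        ]
        return "\n".join(lines)


def _parse_line(fields: list[str], line_no: int) -> ContactPair:
    if len(fields) == 3:
        return ContactPair(int(fields[0]), int(fields[1]), float(fields[2]))
    if len(fields) == 5:
        # tagged dialect: i chain_i j chain_j score
        return ContactPair(int(fields[0]), int(fields[2]), float(fields[4]),
                           chain_i=fields[1], chain_j=fields[3])
    raise ValueError(
        f"line {line_no}: expected 3 columns (i j score) or 5 columns "
        f"(i chain_i j chain_j score), got {len(fields)}: {fields!r}"
    )


def read_contacts(path, dialect: str = "auto") -> list[ContactPair]:
    """Read a delimited coupling list (whitespace, comma or tab separated).

    Two dialects are supported: minimal ``i j score`` and tagged
    ``i chain_i j chain_j score``.  A single header row is auto-detected
    (first column non-numeric) and skipped.  Malformed lines raise with the
    offending line number.
    """
    if dialect not in ("auto", "minimal", "tagged"):
        raise ValueError(f"unknown dialect {dialect!r}")
    pairs: list[ContactPair] = []
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.replace(",", " ").replace("\t", " ").split()
            if line_no == 1:
                try:
                    int(fields[0])
                except ValueError:
                    continue  # header row
            if dialect == "minimal" and len(fields) != 3:
                raise ValueError(f"line {line_no}: minimal dialect needs 3 columns")
            if dialect == "tagged" and len(fields) != 5:
                raise ValueError(f"line {line_no}: tagged dialect needs 5 columns")
            pairs.append(_parse_line(fields, line_no))
    if not pairs:
        warnings.warn(f"no contact pairs found in {path}", stacklevel=2)
    return pairs


def write_contacts(path, pairs: list[ContactPair]) -> None:
    """Write pairs as delimited text; tagged dialect iff any pair is inter-chain."""
    tagged = any(not p.same_chain or p.chain_i != "A" for p in pairs)
    with open(path, "w") as fh:
        for p in pairs:
            if tagged:
                fh.write(f"{p.res_i}\t{p.chain_i}\t{p.res_j}\t{p.chain_j}\t{p.score!r}\n")
            else:
                fh.write(f"{p.res_i}\t{p.res_j}\t{p.score!r}\n")


def top_n(pairs: list[ContactPair], n: int,
          min_separation: int = DEFAULT_MIN_SEPARATION) -> list[ContactPair]:
    """Top-``n`` pairs by score after removing near-diagonal same-chain pairs.

    Sorting is by score descending with (res_i, res_j) ascending as the tie
    rule, so the selection is reproducible regardless of input order.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    eligible = [
        p for p in pairs
        if not (p.same_chain and p.separation < min_separation)
    ]
    eligible.sort(key=lambda p: (-p.score, p.res_i, p.res_j, p.chain_i, p.chain_j))
    return eligible[:n]


def satisfaction(models: dict[str, BackboneModel] | BackboneModel,
                 pairs: list[ContactPair],
                 threshold: float = DEFAULT_THRESHOLD) -> SatisfactionReport:
    """Score a pair list against one or more chains.

    For every pair whose both residues are present in the supplied models the
    Cα–Cα Euclidean distance is computed (across chains when the tags
    differ); a pair is satisfied when the distance is ≤ ``threshold``.
    Raises if no pair is resolvable (the fraction would be undefined).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if isinstance(models, BackboneModel):
        models = {"A": models}

    satisfied = 0
    distances: list[float] = []
    violations: list[tuple[ContactPair, float]] = []
    unresolved: list[ContactPair] = []
    for p in pairs:
        mi = models.get(p.chain_i)
        mj = models.get(p.chain_j)
        if (mi is None or mj is None
                or not mi.has_residue(p.res_i) or not mj.has_residue(p.res_j)):
            unresolved.append(p)
            continue
        d = float(np.linalg.norm(mi.ca[mi.index_of(p.res_i)] - mj.ca[mj.index_of(p.res_j)]))
        distances.append(d)
        if d <= threshold:
            satisfied += 1
        else:
            violations.append((p, d))
    if not distances:
        raise ValueError("no resolvable pairs: satisfaction fraction undefined")
    return SatisfactionReport(
        n_pairs=len(distances),
        n_satisfied=satisfied,
        threshold=threshold,
        mean_distance=float(np.mean(distances)),
        violations=violations,
        unresolved=unresolved,
    )
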