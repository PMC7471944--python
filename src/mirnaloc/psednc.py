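"""Pseudo dinucleotide composition (PseDNC) encoding.

PseDNC augments the 16 normalized dinucleotide frequencies g_tau with lambda
sequence-order correlation factors alpha_j, each the mean squared property
distance between dinucleotides at offset j along the sequence, weighted by a
factor w and jointly normalized so the full vector sums to one:

    v_tau = g_tau / Z              (tau = 1..16)
    v_tau = w * alpha_{tau-16} / Z (tau = 17..16+lambda)

with Z = sum_i g_i + w * sum_j alpha_j.  The correlation between two
dinucleotides is R(d1, d2) = (1/mu) * sum_f [P_f(d1) - P_f(d2)]^2 over the
mu = 15 standardized properties, and

    alpha_j = (1/(L-j-1)) * sum_{i=1}^{L-j-1} R(D_i, D_{i+j}),

where D_i is the dinucleotide starting at position i of a length-L sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from mirnaloc.properties import DINUCLEOTIDES, PropertyTable, load_default_table, standardize
from mirnaloc.sequence_io import RnaSequence, SequenceError, dinucleotides

_DIN_INDEX = {d: i for i, d in enumerate(DINUCLEOTIDES)}


def _default_table() -> PropertyTable:
    return standardize(load_default_table())


@dataclass(frozen=True)
class PseDncConfig:
    """PseDNC parameters: lambda pseudo components, weight w, property table.

    lam defaults to 2 (total combined feature width 33 with DiPro) and w to
    0.1.  The table must be the standardized view; `use_raw_properties`
    switches the correlation to raw values for sensitivity checks.
    """

    lam: int = 2
    w: float = 0.1
    table: PropertyTable = field(default_factory=_default_table)
    use_raw_properties: bool = False

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError(f"lambda must be >= 0, got {self.lam}")
        if not (0 < self.w <= 1):
            raise ValueError(f"weight w must be in (0, 1], got {self.w}")
        if not self.use_raw_properties and not self.table.standardized:
            raise ValueError("PseDNC requires the standardized property table")


def correlation(d1: str, d2: str, table: PropertyTable) -> float:
    """Mean squared property difference R between two dinucleotides."""
    p1, p2 = table.row(d1), table.row(d2)
    diff = p1 - p2
    return float(diff @ diff) / len(diff)


def _correlation_matrix(table: PropertyTable) -> np.ndarray:
    """Precomputed 16x16 matrix of R values over all dinucleotide pairs."""
    vals = table.values.to_numpy()
    diff = vals[:, None, :] - vals[None, :, :]
    return np.einsum("ijk,ijk->ij", diff, diff) / vals.shape[1]


def tier_correlation_factor(seq: RnaSequence, j: int, table: PropertyTable) -> float:
    """alpha_j: mean correlation between dinucleotides at offset j."""
    if j < 1:
        raise ValueError(f"tier j must be >= 1, got {j}")
    dins = dinucleotides(seq)
    n_terms = len(dins) - j  # = L - j - 1
    if n_terms < 1:
        raise SequenceError(
            f"sequence {seq.id!r} of length {seq.length} is too short for tier j={j}"
        )
    total = sum(correlation(dins[i], dins[i + j], table) for i in range(n_terms))
    return total / n_terms


def psednc_encode(seq: RnaSequence, cfg: PseDncConfig) -> np.ndarray:
    """Encode one sequence as its PseDNC vector of length 16 + lambda."""
    if seq.length < cfg.lam + 2:
        raise SequenceError(
            f"sequence {seq.id!r} of length {seq.length} is too short for "
            f"lambda={cfg.lam} (need L >= {cfg.lam + 2})"
        )
    dins = dinucleotides(seq)
    idx = np.array([_DIN_INDEX[d] for d in dins])
    g = np.bincount(idx, minlength=16) / len(dins)  # sums to 1

    rmat = _correlation_matrix(cfg.table)
    alphas = np.empty(cfg.lam)
    for j in range(1, cfg.lam + 1):
        alphas[j - 1] = rmat[idx[:-j], idx[j:]].mean()

    z = g.sum() + cfg.w * alphas.sum()
    return np.concatenate([g, cfg.w * alphas]) / z


def psednc_feature_names(lam: int) -> list[str]:
    return [f"psednc_{d}" for d in DINUCLEOTIDES] + [
        f"psednc_alpha{j}" for j in range(1, lam + 1)
    ]


def encode_features(
    seqs: Sequence[RnaSequence],
    cfg: PseDncConfig | None = None,
    raw_table: PropertyTable | None = None,
) -> pd.DataFrame:
    """Combined feature matrix: [DiPro 15 | PseDNC 16+lambda] per sequence.

    With the default lambda = 2 the matrix is n x 33.  `raw_table` is the
    unstandardized table the DiPro block averages (default: the embedded
    asset); the PseDNC block uses the standardized table inside `cfg`.
    Per-sequence encoder failures are aggregated into a single error naming
    the offending ids.
    """
    from mirnaloc.properties import dipro_encode, load_default_table

    if cfg is None:
        cfg = PseDncConfig()
    if raw_table is None:
        raw_table = load_default_table()
    columns = [f"dipro_{p}" for p in raw_table.property_names] + psednc_feature_names(cfg.lam)

    rows, ids, failures = [], [], []
    for seq in seqs:
        try:
            dipro = dipro_encode(seq, raw_table).to_numpy()
            pse = psednc_encode(seq, cfg)
        except (SequenceError, KeyError) as exc:
            failures.append(f"{seq.id}: {exc}")
            continue
        rows.append(np.concatenate([dipro, pse]))
        ids.append(seq.id)
    if failures:
        raise SequenceError(
            "encoding failed for %d sequence(s):\n%s" % (len(failures), "\n".join(failures))
        )
    return pd.DataFrame(rows, index=pd.Index(ids, name="id"), columns=columns)
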