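"""Per-sample alpha diversity: Shannon entropy, Chao1 richness, Good's coverage.

Shannon defaults to log base 2; Chao1 defaults to the bias-corrected variant
S_obs + F1(F1-1)/(2(F2+1)), which stays defined when no doubletons are
observed.  Good's coverage 1 - F1/N estimates the fraction of the community
captured at the sampling depth (F1 = singleton taxa, N = total reads).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .abundance import AbundanceTable, DegenerateSampleError

__all__ = [
    "shannon_index",
    "chao1",
    "goods_coverage",
    "observed_taxa",
    "diversity_profile",
    "write_profile",
]


def _counts_vector(counts) -> np.ndarray:
    vec = np.asarray(counts, dtype=float).ravel()
    if (vec < 0).any():
        raise ValueError("counts must be nonnegative")
    if vec.sum() <= 0:
        raise DegenerateSampleError("sample has zero total counts")
    return vec


def shannon_index(counts, base: float = 2.0) -> float:
    """Shannon entropy H = -sum p_i log_base p_i over taxa with p_i > 0."""
    vec = _counts_vector(counts)
    p = vec[vec > 0] / vec.sum()
    return float(-(p * np.log(p)).sum() / np.log(base))


def observed_taxa(counts) -> int:
    vec = _counts_vector(counts)
    return int((vec > 0).sum())


def chao1(counts, bias_corrected: bool = True) -> float:
    """Chao1 richness estimate from singleton (F1) and doubleton (F2) counts."""
    vec = _counts_vector(counts)
    if not np.allclose(vec, np.round(vec)):
        raise ValueError("chao1 requires integer counts")
    s_obs = float((vec > 0).sum())
    f1 = float((vec == 1).sum())
    f2 = float((vec == 2).sum())
    if bias_corrected:
        return s_obs + f1 * (f1 - 1.0) / (2.0 * (f2 + 1.0))
    if f1 == 0:
        return s_obs
    if f2 == 0:
        raise ZeroDivisionError("classic Chao1 undefined with singletons but no doubletons")
    return s_obs + f1 * f1 / (2.0 * f2)


def goods_coverage(counts) -> float:
    """Good's coverage 1 - F1/N, the estimated sampled fraction of the community."""
    vec = _counts_vector(counts)
    if not np.allclose(vec, np.round(vec)):
        raise ValueError("Good's coverage requires integer counts")
    f1 = float((vec == 1).sum())
    return 1.0 - f1 / vec.sum()


def diversity_profile(table: AbundanceTable, shannon_base: float = 2.0) -> pd.DataFrame:
    """Per-sample table of observed taxa, Shannon, Chao1 and Good's coverage."""
    if table.kind != "counts":
        raise ValueError("diversity profile requires a counts table")
    rows = []
    for sample_id, row in zip(table.sample_ids, table.values):
        rows.append(
            {
                "sample_id": sample_id,
                "observed_taxa": observed_taxa(row),
                "shannon": shannon_index(row, base=shannon_base),
                "chao1": chao1(row),
                "goods_coverage": goods_coverage(row),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def write_profile(profile: pd.DataFrame, path: str | Path, header_lines: Iterable[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        profile.to_csv(fh, sep="\t")
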