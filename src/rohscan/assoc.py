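"""Per-locus association of a continuous phenotype with ROH state.

At each marker the regressor is a binary indicator: does the individual's
ROH cover this position.  An ordinary least-squares fit

    phenotype = b0 + b1 * state

is tested with a two-sided t-test on b1 (n - 2 df).  For a binary
regressor b1 equals the difference of phenotype means between covered and
uncovered individuals, so the scan is a per-marker two-group comparison
with genome-wide Bonferroni control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datamodel import GenotypeDataset
from .islands import roh_coverage_matrix
from .roh_detect import ROHSegment

__all__ = ["AssocConfig", "AssocRecord", "roh_state_matrix", "assoc_scan"]


@dataclass(frozen=True)
class AssocConfig:
    """Scan settings.

    ``bonferroni_p`` is the genome-wide significance threshold on the raw
    p-value (default the conventional 1.5e-6 used for ~150K arrays;
    override with 0.05 / n_tests to recompute).  Markers where either ROH
    state has fewer than ``min_group_size`` phenotyped samples are skipped
    to avoid degenerate fits.
    """

    bonferroni_p: float = 1.5e-6
    min_group_size: int = 5

    def __post_init__(self):
        if not (0 < self.bonferroni_p < 1):
            raise ValueError("bonferroni_p must be in (0, 1)")
        if self.min_group_size < 1:
            raise ValueError("min_group_size must be >= 1")


@dataclass(frozen=True)
class AssocRecord:
    chrom: str
    bp: int
    marker_id: str
    n_used: int
    beta: float
    se: float
    t_stat: float
    p_value: float
    significant: bool
    degenerate: bool = False  # zero residual variance; p set to 0


def roh_state_matrix(
    segments: list[ROHSegment], dataset: GenotypeDataset
) -> np.ndarray:
    """Per-(sample, marker) 0/1 indicator of ROH coverage.

    Column means of this matrix equal the island support profile by
    construction.
    """
    return roh_coverage_matrix(segments, dataset).astype(np.int8)


def assoc_scan(
    state_matrix: np.ndarray,
    phenotype: pd.Series | dict | np.ndarray,
    dataset: GenotypeDataset,
    config: AssocConfig | None = None,
) -> list[AssocRecord]:
    """OLS scan of phenotype on ROH state at every eligible marker.

    ``phenotype`` maps sample id to trait value (Series/dict), or is an
    array aligned with ``dataset.samples``; NaN values drop the sample.
    Markers with only one ROH state among phenotyped samples, or with an
    undersized group, are skipped.  A constant phenotype leaves every
    marker degenerate and returns an empty scan.
    """
    config = config or AssocConfig()
    if isinstance(phenotype, dict):
        phenotype = pd.Series(phenotype)
    if isinstance(phenotype, pd.Series):
        y = np.array([phenotype.get(s, np.nan) for s in dataset.samples], dtype=float)
    else:
        y = np.asarray(phenotype, dtype=float)
        if y.size != dataset.n_samples:
            raise ValueError("phenotype array not aligned with samples")
    ok = ~np.isnan(y)
    if ok.sum() < 3:
        raise ValueError("need phenotype values for at least 3 samples")
    y = y[ok]
    X = np.asarray(state_matrix, dtype=np.int8)[ok, :]
    n = y.size

    records: list[AssocRecord] = []
    n1 = X.sum(axis=0)
    n0 = n - n1
    for j, m in enumerate(dataset.markers):
        if n1[j] < config.min_group_size or n0[j] < config.min_group_size:
            continue
        x = X[:, j].astype(bool)
        y1, y0 = y[x], y[~x]
        beta = y1.mean() - y0.mean()
        sse = ((y1 - y1.mean()) ** 2).sum() + ((y0 - y0.mean()) ** 2).sum()
        df = n - 2
        if sse <= 0:
            records.append(
                AssocRecord(
                    m.chrom, m.bp, m.id, n, float(beta), 0.0,
                    math.inf if beta else 0.0,
                    0.0 if beta else 1.0,
                    significant=bool(beta) and 0.0 < config.bonferroni_p,
                    degenerate=True,
                )
            )
            continue
        se = math.sqrt(sse / df * (1.0 / n1[j] + 1.0 / n0[j]))
        t = beta / se
        p = 2.0 * sps.t.sf(abs(t), df)
        p = min(p, 1.0)
        records.append(
            AssocRecord(
                m.chrom, m.bp, m.id, n, float(beta), float(se), float(t),
                float(p), significant=p < config.bonferroni_p,
            )
        )
    return records


def assoc_frame(records: list[AssocRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])
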