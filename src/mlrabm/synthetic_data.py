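"""Synthetic fixtures: donor cohorts and pseudo ex vivo dose-response data.

Every generated donor carries a *hidden* ground-truth sigmoid (bottom, span,
log-EC50) from which noisy triplicate titration measurements can be
produced, so recovery of EC50s, RANSAC screens and agreement analyses can
all be tested end to end without any laboratory data.  Phenotype values
emulate the observed donor-to-donor heterogeneity of baseline PD-1/PD-L1
expression; measurement noise is Gaussian and homoscedastic in span units
(the simplest model consistent with triplicate s.e.m. bars), with a
heavier-tailed contamination option for robustness stress tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .experiment import DEFAULT_DOSE_GRID, DoseResponseTable
from .model_core import DonorPhenotype

__all__ = [
    "SyntheticCohortSpec",
    "DonorTruth",
    "generate_cohort",
    "generate_exvivo_table",
]


class SyntheticCohortSpec(BaseModel):
    """Distributional description of a synthetic donor cohort."""

    model_config = ConfigDict(extra="forbid")

    n_donors: int = Field(default=27, ge=0)
    # Phenotype heterogeneity (log-normal across donors for positive stats).
    pct_pd1_mean: float = Field(default=30.0, gt=0.0, le=100.0)
    pct_pd1_cv: float = Field(default=0.35, ge=0.0)
    geo_mean_pd1_mean: float = Field(default=5.0, gt=0.0)
    geo_mean_pd1_cv: float = Field(default=0.4, ge=0.0)
    pct_pdl1_mean: float = Field(default=8.0, gt=0.0, le=100.0)
    pct_pdl1_cv: float = Field(default=0.5, ge=0.0)
    geo_mean_pdl1_mean: float = Field(default=3.0, gt=0.0)
    geo_mean_pdl1_cv: float = Field(default=0.4, ge=0.0)
    # Hidden per-donor dose-response truths.
    bottom_range: tuple[float, float] = (10.0, 35.0)
    span_range: tuple[float, float] = (8.0, 25.0)
    log_ec50_range: tuple[float, float] = (-11.5, -10.0)
    # Measurement model.
    noise_sigma_frac: float = Field(default=0.05, ge=0.0, description="replicate noise as fraction of span")
    outlier_fraction: float = Field(default=0.0, ge=0.0, le=1.0)
    seed: int = 0


@dataclass(frozen=True)
class DonorTruth:
    """Hidden ground-truth sigmoid of one synthetic donor."""

    donor_id: str
    bottom: float
    top: float
    ec50: float

    @property
    def span(self) -> float:
        return self.top - self.bottom

    def response(self, doses) -> np.ndarray:
        doses = np.asarray(doses, dtype=float)
        return self.bottom + self.span * doses / (doses + self.ec50)


def _lognormal(rng, mean, cv, size):
    if cv <= 0:
        return np.full(size, mean)
    s2 = np.log1p(cv * cv)
    return rng.lognormal(np.log(mean) - 0.5 * s2, np.sqrt(s2), size=size)


def generate_cohort(
    spec: SyntheticCohortSpec,
) -> tuple[list[DonorPhenotype], list[DonorTruth]]:
    """Sample a reproducible cohort of donor phenotypes with hidden truths.

    Phenotype statistics stay within physiologic bounds (percentages capped
    at 95 %); the true sigmoid parameters are drawn uniformly from the spec
    ranges and returned separately for recovery tests.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_donors
    pct_pd1 = np.clip(_lognormal(rng, spec.pct_pd1_mean, spec.pct_pd1_cv, n), 0.5, 95.0)
    pct_pd1_cd8 = np.clip(pct_pd1 * rng.uniform(0.8, 1.2, n), 0.5, 95.0)
    gm_pd1 = _lognormal(rng, spec.geo_mean_pd1_mean, spec.geo_mean_pd1_cv, n)
    pct_pdl1 = np.clip(_lognormal(rng, spec.pct_pdl1_mean, spec.pct_pdl1_cv, n), 0.5, 95.0)
    gm_pdl1 = _lognormal(rng, spec.geo_mean_pdl1_mean, spec.geo_mean_pdl1_cv, n)
    bottoms = rng.uniform(*spec.bottom_range, n)
    spans = rng.uniform(*spec.span_range, n)
    log_ec50 = rng.uniform(*spec.log_ec50_range, n)
    days = rng.choice([4, 5], size=n)

    donors, truths = [], []
    for i in range(n):
        did = f"SD{i + 1:03d}"
        donors.append(
            DonorPhenotype(
                donor_id=did,
                pct_pd1_cd4=float(pct_pd1[i]),
                pct_pd1_cd8=float(pct_pd1_cd8[i]),
                geo_mean_pd1=float(gm_pd1[i]),
                pct_pdl1_mono=float(pct_pdl1[i]),
                geo_mean_pdl1=float(gm_pdl1[i]),
                mlr_days=int(days[i]),
            )
        )
        truths.append(
            DonorTruth(
                donor_id=did,
                bottom=float(bottoms[i]),
                top=float(bottoms[i] + spans[i]),
                ec50=float(10.0 ** log_ec50[i]),
            )
        )
    return donors, truths


def generate_exvivo_table(
    truth: DonorTruth,
    doses: Sequence[float] = DEFAULT_DOSE_GRID,
    n_replicates: int = 3,
    noise_sigma_frac: float = 0.05,
    seed: int = 0,
    outlier_fraction: float = 0.0,
    mlr_days: int = 4,
) -> DoseResponseTable:
    """Noisy triplicate titration measurements from a known sigmoid.

    ``response = truth(dose) + N(0, sigma * span)`` truncated to [0, 100];
    with ``outlier_fraction > 0`` that share of measurements is replaced by
    gross heavy-tailed errors (5-sigma scale) for robustness tests.
    """
    if noise_sigma_frac < 0:
        raise ValueError("noise sigma must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    time_h = mlr_days * 24.0
    for dose in doses:
        clean = float(truth.response(dose))
        for rep in range(n_replicates):
            val = clean + rng.normal(0.0, noise_sigma_frac * truth.span)
            if outlier_fraction > 0 and rng.random() < outlier_fraction:
                val = clean + rng.standard_cauchy() * 5.0 * noise_sigma_frac * truth.span
            val = float(np.clip(val, 0.0, 100.0))
            rows.append(
                {
                    "donor_id": truth.donor_id,
                    "condition": f"anti_pdl1_{dose:.1e}",
                    "dose_M": float(dose),
                    "replicate": rep,
                    "time_h": time_h,
                    "pct_pd1_cd4": val,
                    "pct_pd1_cd8": val,
                    "ifng": float(np.clip(clean + rng.normal(0.0, noise_sigma_frac * truth.span), 0.0, None)),
                    "pct_pdl1_mono": np.nan,
                }
            )
    df = pd.DataFrame(rows, columns=DoseResponseTable.COLUMNS)
    return DoseResponseTable(donor_id=truth.donor_id, df=df)
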