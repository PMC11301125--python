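"""Cumulative DIF impact on total scores via expected-test-score curves.

The expected test score at latent severity theta is the sum over items of
the item response functions — the model-implied number of criteria a
respondent at that severity endorses.  Computing it per group from a fitted
(or published) item bank and taking the between-group difference shows how
much DIF shifts the total score that clinicians actually use: two groups
with identical parameters give identically overlapping curves, and the
maximum absolute difference over the latent range is the headline impact
number.

A secondary, focal-density-weighted mean absolute difference is also
reported; unlike the max it reflects where focal-group respondents actually
sit on the latent scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import ItemBank, LatentDistribution


def expected_test_score(bank: ItemBank, group: str, theta: np.ndarray) -> np.ndarray:
    """Model-implied total score for one group at each latent value."""
    a, b = bank.resolve(group)
    theta = np.asarray(theta, dtype=float)
    p = 1.0 / (1.0 + np.exp(-a[None, :] * (theta[:, None] - b[None, :])))
    return p.sum(axis=1)


@dataclass
class ImpactCurve:
    """Per-group expected-score curves on a common grid and their difference."""

    theta: np.ndarray
    reference_group: str
    focal_group: str
    expected_reference: np.ndarray
    expected_focal: np.ndarray

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)

    @property
    def difference(self) -> np.ndarray:
        """Focal minus reference expected score at each node."""
        return self.expected_focal - self.expected_reference

    @property
    def max_abs_difference(self) -> float:
        return float(np.abs(self.difference).max())

    @property
    def argmax_theta(self) -> float:
        return float(self.theta[int(np.abs(self.difference).argmax())])

    def weighted_mean_abs_difference(self, latent: LatentDistribution) -> float:
        """Mean |difference| weighted by the focal group's latent density."""
        mean, var = latent.moments(self.focal_group)
        w = np.exp(-((self.theta - mean) ** 2) / (2.0 * var))
        w /= w.sum()
        return float(w @ np.abs(self.difference))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "theta": self.theta,
                f"expected_{self.reference_group}": self.expected_reference,
                f"expected_{self.focal_group}": self.expected_focal,
                "difference": self.difference,
            }
        )


def impact_curve(
    bank: ItemBank,
    theta_range: tuple[float, float] = (-4.0, 4.0),
    step: float = 0.01,
) -> ImpactCurve:
    """Expected-score curves for both groups of a bank on a regular theta grid."""
    lo, hi = theta_range
    if not hi > lo or step <= 0:
        raise ValidationError("theta_range must be increasing and step positive")
    theta = np.arange(lo, hi + step / 2.0, step)
    return ImpactCurve(
        theta,
        bank.reference_group,
        bank.focal_group,
        expected_test_score(bank, bank.reference_group, theta),
        expected_test_score(bank, bank.focal_group, theta),
    )


def export_curve(
    curve: ImpactCurve,
    path: str | Path,
    figure_path: str | Path | None = None,
) -> None:
    """Write the plot-ready table; optionally render the two-line figure."""
    curve.to_frame().to_csv(path, index=False)
    if figure_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(curve.theta, curve.expected_reference, label=curve.reference_group)
        ax.plot(curve.theta, curve.expected_focal, label=curve.focal_group, linestyle="--")
        ax.set_xlabel("Latent AUD severity (theta)")
        ax.set_ylabel("Expected number of criteria endorsed")
        ax.legend()
        fig.tight_layout()
        fig.savefig(figure_path, dpi=150)
        plt.close(fig)


def read_curve(path: str | Path) -> ImpactCurve:
    """Round-trip companion to :func:`export_curve`."""
    frame = pd.read_csv(path)
    expected_cols = [c for c in frame.columns if c.startswith("expected_")]
    if len(expected_cols) != 2:
        raise ValidationError(f"{path}: expected exactly two expected_* columns")
    ref_col, foc_col = expected_cols
    return ImpactCurve(
        frame["theta"].to_numpy(),
        ref_col.removeprefix("expected_"),
        foc_col.removeprefix("expected_"),
        frame[ref_col].to_numpy(),
        frame[foc_col].to_numpy(),
    )
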