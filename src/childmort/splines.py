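"""B-spline bases for log-mortality trend models.

The trend component of every model in this package is a linear combination of
B-spline basis functions evaluated at decimal years.  Bases are clamped
(boundary knots repeated ``degree + 1`` times) so that the partition-of-unity
identity holds over the whole support, which in turn means a basis with
coefficients sampled from a linear function of the Greville abscissae
reproduces that linear function exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline


@dataclass(frozen=True)
class SplineBasis:
    """Clamped B-spline basis on a fixed year range.

    Parameters
    ----------
    knots
        Full knot vector including the repeated boundary knots.
    degree
        Polynomial degree of the basis (3 for cubic).
    """

    knots: np.ndarray
    degree: int

    def __post_init__(self) -> None:
        interior = self.knots[self.degree : len(self.knots) - self.degree]
        if np.any(np.diff(interior) <= 0):
            raise ValueError("interior knots must be strictly increasing")

    @property
    def n_coef(self) -> int:
        return len(self.knots) - self.degree - 1

    @property
    def support(self) -> tuple[float, float]:
        return float(self.knots[self.degree]), float(self.knots[-self.degree - 1])

    @property
    def greville(self) -> np.ndarray:
        """Greville abscissae: the year each coefficient 'lives' at."""
        k = self.degree
        t = self.knots
        return np.array([t[i + 1 : i + 1 + k].mean() if k else t[i] for i in range(self.n_coef)])

    def design_matrix(self, years: np.ndarray) -> np.ndarray:
        """Dense (n_years, n_coef) matrix of basis weights.

        Raises if any year falls outside the basis support.
        """
        years = np.atleast_1d(np.asarray(years, dtype=float))
        lo, hi = self.support
        if years.min() < lo - 1e-9 or years.max() > hi + 1e-9:
            raise ValueError(
                f"years [{years.min()}, {years.max()}] outside basis support [{lo}, {hi}]"
            )
        years = np.clip(years, lo, hi)
        dm = BSpline.design_matrix(years, self.knots, self.degree)
        return np.asarray(dm.todense())

    def difference_matrix(self, order: int = 1) -> np.ndarray:
        """First- (or higher-) order difference operator on coefficients."""
        d = np.eye(self.n_coef)
        for _ in range(order):
            d = np.diff(d, axis=0)
        return d


def build_spline_basis(
    year_start: float,
    year_end: float,
    knot_spacing: float = 2.5,
    degree: int = 3,
) -> SplineBasis:
    """Build a clamped B-spline basis covering ``[year_start, year_end]``.

    ``knot_spacing`` is in years; the last interval is shortened if the span
    is not an exact multiple.  Fails if the span yields fewer than
    ``degree + 1`` knot intervals, which would leave the trend under-determined.
    """
    if year_end <= year_start:
        raise ValueError("year_end must exceed year_start")
    n_intervals = int(np.ceil((year_end - year_start) / knot_spacing - 1e-9))
    if n_intervals < degree + 1:
        raise ValueError(
            f"{n_intervals} knot intervals < degree+1={degree + 1}; "
            "extend the year range or reduce knot_spacing"
        )
    interior = np.minimum(year_start + knot_spacing * np.arange(n_intervals + 1), year_end)
    interior[-1] = year_end
    knots = np.concatenate(
        [np.full(degree, year_start), interior, np.full(degree, year_end)]
    )
    return SplineBasis(knots=knots, degree=degree)
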