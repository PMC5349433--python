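"""Chance probability of a chain's summed real-space correlation coefficients.

The per-residue real-space correlation coefficient (RSCC) measures how well
a modelled residue agrees with the observed electron density; values near 1
indicate a good fit.  Pooling the RSCC values of every residue of every
scored peptide-ligand chain gives an empirical probability density f₁ on
[-1, 1] (binned at 0.01).  Treating a chain of length n as n independent,
identically distributed draws from f₁, the density fₙ of the sum
Sₙ = R₁ + … + Rₙ is the n-fold self-convolution of f₁, computed by
iterated discrete convolution on the common grid.  The chance probability
of observing a chain's actual RSCC sum sₙ *or any lower sum* is then the
cumulative distribution P(Sₙ ≤ sₙ): small values flag chains whose overall
density fit is improbably poor under the cohort-wide distribution.

The independence assumption ignores correlation between neighbouring
residues' density fit; it makes the statistic conservative in the sense of
a smooth, well-defined null rather than an exact one.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "EmpiricalPDF",
    "ConvolvedPDF",
    "ChainProbability",
    "build_empirical_pdf",
    "convolve_pdf",
    "rscc_sum_probability",
    "chain_rscc_probability",
]

#: chains are < 50 residues by definition; the cap bounds grid growth
MAX_CONVOLUTION_ORDER = 60


@dataclass(frozen=True)
class EmpiricalPDF:
    """Binned probability density on the fixed support [-1, 1].

    ``mass[i]`` is the probability of the bin centred at
    ``support_min + (i + 1/2)·bin_width``.  Masses sum to one.
    """

    bin_width: float
    support_min: float
    support_max: float
    mass: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "mass", np.asarray(self.mass, dtype=float))
        n_bins = round((self.support_max - self.support_min) / self.bin_width)
        if len(self.mass) != n_bins:
            raise ValueError(f"expected {n_bins} bins, got {len(self.mass)}")
        if np.any(self.mass < 0):
            raise ValueError("negative probability mass")
        if abs(self.mass.sum() - 1.0) > 1e-9:
            raise ValueError(f"mass sums to {self.mass.sum()}, not 1")

    @property
    def centers(self) -> np.ndarray:
        n = len(self.mass)
        return self.support_min + (np.arange(n) + 0.5) * self.bin_width

    def mean(self) -> float:
        return float(np.dot(self.centers, self.mass))

    def var(self) -> float:
        mu = self.mean()
        return float(np.dot((self.centers - mu) ** 2, self.mass))

    def to_text(self, path: str | Path) -> None:
        """Write as two tab-separated columns: bin centre, mass."""
        arr = np.column_stack([self.centers, self.mass])
        header = (
            f"bin_width={self.bin_width} support_min={self.support_min} "
            f"support_max={self.support_max} n_samples={self.n_samples}"
        )
        np.savetxt(path, arr, delimiter="\t", header=header, fmt="%.10g")

    @classmethod
    def from_text(cls, path: str | Path) -> "EmpiricalPDF":
        with open(path) as fh:
            first = fh.readline()
        meta = dict(
            kv.split("=") for kv in first.lstrip("#").split() if "=" in kv
        )
        arr = np.loadtxt(path, delimiter="\t")
        return cls(
            bin_width=float(meta["bin_width"]),
            support_min=float(meta["support_min"]),
            support_max=float(meta["support_max"]),
            mass=arr[:, 1],
            n_samples=int(meta.get("n_samples", 0)),
        )


@dataclass(frozen=True)
class ConvolvedPDF:
    """Density of the sum of ``n`` i.i.d. draws from an :class:`EmpiricalPDF`."""

    n: int
    bin_width: float
    support_min: float  # n * f1.support_min
    mass: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "mass", np.asarray(self.mass, dtype=float))

    @property
    def grid(self) -> np.ndarray:
        return self.support_min + (np.arange(len(self.mass)) + 0.5 * self.n) * self.bin_width

    @property
    def support_max(self) -> float:
        """Upper edge of the last populated bin."""
        return self.support_min + (len(self.mass) - 0.5 + 0.5 * self.n) * self.bin_width

    @property
    def cdf(self) -> np.ndarray:
        return np.cumsum(self.mass)


@dataclass(frozen=True)
class ChainProbability:
    """P(Sₙ ≤ sₙ): chance of a chain's RSCC sum or any lower sum."""

    n: int
    rscc_sum: float
    probability: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(f"probability {self.probability} outside [0, 1]")


def build_empirical_pdf(values, bin_width: float = 0.01) -> EmpiricalPDF:
    """Histogram RSCC values into a unit-mass density on [-1, 1].

    Values exactly at 1 are attributed to the last bin.  A value outside
    [-1, 1] raises, identifying the offending index.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("build_empirical_pdf requires at least one value")
    bad = np.nonzero((values < -1.0) | (values > 1.0))[0]
    if bad.size:
        raise ValueError(
            f"RSCC value {values[bad[0]]} at position {bad[0]} outside [-1, 1]"
        )
    n_bins = round(2.0 / bin_width)
    # assign by index arithmetic: a value exactly on a bin boundary belongs
    # to the upper bin (half-open bins), robust to float edge error
    idx = np.floor((values + 1.0) / bin_width + 1e-9).astype(int)
    idx = np.clip(idx, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    return EmpiricalPDF(
        bin_width=bin_width,
        support_min=-1.0,
        support_max=1.0,
        mass=counts / counts.sum(),
        n_samples=int(values.size),
    )


def convolve_pdf(f1: EmpiricalPDF, n: int) -> ConvolvedPDF:
    """n-fold self-convolution of ``f1`` by iterated discrete convolution.

    Each value is attributed to its bin centre, so the sum of ``n`` draws
    lives on the grid ``n·support_min + (k + n/2)·bin_width``.  Mass is
    conserved to well below 1e-6 for all supported orders.
    """
    if n < 1:
        raise ValueError("convolution order n must be >= 1")
    if n > MAX_CONVOLUTION_ORDER:
        raise ValueError(
            f"convolution order {n} exceeds supported maximum {MAX_CONVOLUTION_ORDER}"
        )
    mass = f1.mass.copy()
    for _ in range(n - 1):
        mass = np.convolve(mass, f1.mass)
    return ConvolvedPDF(
        n=n, bin_width=f1.bin_width, support_min=n * f1.support_min, mass=mass
    )


class ConvolutionTable:
    """Caches self-convolution orders of one base density.

    Orders are built incrementally (fₖ = fₖ₋₁ ∗ f₁), so scoring a whole
    cohort against a shared f₁ costs one pass up to the largest chain
    length instead of one independent convolution stack per chain.
    """

    def __init__(self, f1: EmpiricalPDF):
        self.f1 = f1
        self._mass: dict[int, np.ndarray] = {1: f1.mass.copy()}

    def get(self, n: int) -> ConvolvedPDF:
        if n < 1:
            raise ValueError("convolution order n must be >= 1")
        if n > MAX_CONVOLUTION_ORDER:
            raise ValueError(
                f"convolution order {n} exceeds supported maximum {MAX_CONVOLUTION_ORDER}"
            )
        top = max(self._mass)
        while top < n:
            self._mass[top + 1] = np.convolve(self._mass[top], self.f1.mass)
            top += 1
        return ConvolvedPDF(
            n=n,
            bin_width=self.f1.bin_width,
            support_min=n * self.f1.support_min,
            mass=self._mass[n],
        )


def rscc_sum_probability(fn: ConvolvedPDF, s: float) -> ChainProbability:
    """Evaluate P(Sₙ ≤ s) on the convolved grid.

    The CDF is evaluated with linear interpolation inside the containing
    bin (each bin's mass spread uniformly across its width); ``s`` below
    the support gives 0, above gives 1.
    """
    centers = fn.grid
    half = 0.5 * fn.bin_width
    left_edges = centers - half
    cdf = fn.cdf
    lo = left_edges[0]
    hi = centers[-1] + half
    if s <= lo:
        p = 0.0
    elif s >= hi:
        p = 1.0
    else:
        k = int(np.searchsorted(left_edges, s, side="right")) - 1
        below = cdf[k - 1] if k > 0 else 0.0
        p = below + fn.mass[k] * (s - left_edges[k]) / fn.bin_width
    return ChainProbability(n=fn.n, rscc_sum=s, probability=float(min(max(p, 0.0), 1.0)))


def chain_rscc_probability(
    f1: EmpiricalPDF, rscc_values, table: ConvolutionTable | None = None
) -> ChainProbability:
    """Chance probability of a chain's observed RSCC sum under ``f1``.

    ``n`` is the number of residues with an observed RSCC (missing residues
    are excluded upstream); a single-residue chain is scored by the f₁ CDF
    directly.  Passing a :class:`ConvolutionTable` built on ``f1`` reuses
    convolution orders across chains.
    """
    values = np.asarray(rscc_values, dtype=float)
    if values.size == 0:
        raise ValueError("chain has no observed RSCC values")
    n = int(values.size)
    fn = table.get(n) if table is not None else convolve_pdf(f1, n)
    return rscc_sum_probability(fn, float(values.sum()))
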