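"""Parameter registry and probabilistic-sensitivity distributions.

Every model input lives in a :class:`ParameterRegistry` as a
:class:`ParameterSpec` holding the point estimate and, for the distributed
parameters, the theoretical family assigned by the usual PSA conventions:

* **beta** for dichotomous event probabilities and state utilities,
* **Dirichlet** for polytomous shares (the split of switchers across DMTs),
* **gamma** for resource-consumption volumes and EDSS scores,
* **normal** for non-drug unit costs (truncated at zero when sampling),
* **fixed** for drug prices/posology and structural settings, optionally
  with a (low, high) range so one-way sensitivity analysis can vary them.

Dispersion is given either as a standard error or as a coefficient of
variation on the mean (``se = |mean| * cv``).  All fits are by the method
of moments, so the fitted distribution reproduces the registry's point
estimate and standard error.
"""

from __future__ import annotations


from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InfeasibleMomentsError, ValidationError

FAMILIES = ("BETA", "DIRICHLET", "GAMMA", "NORMAL", "FIXED")

_Z975 = stats.norm.ppf(0.975)


def se_from_cv(mean: float, cv: float) -> float:
    """Standard error implied by a coefficient of variation on the mean."""
    if cv < 0:
        raise ValidationError(f"coefficient of variation must be >= 0, got {cv}")
    return abs(mean) * cv


def fit_beta(mean: float, se: float) -> tuple[float, float]:
    """Method-of-moments (alpha, beta) for a beta distribution.

    Requires ``0 < mean < 1`` and ``se**2 < mean * (1 - mean)``.
    """
    if not 0.0 < mean < 1.0:
        raise ValidationError(f"beta mean must lie in (0, 1), got {mean}")
    v = se * se
    if v >= mean * (1.0 - mean):
        raise InfeasibleMomentsError(
            f"beta moments infeasible: se^2={v:.6g} >= mean(1-mean)="
            f"{mean * (1 - mean):.6g}"
        )
    if v == 0.0:
        raise InfeasibleMomentsError("beta fit requires se > 0")
    nu = mean * (1.0 - mean) / v - 1.0
    return mean * nu, (1.0 - mean) * nu


def fit_gamma(mean: float, se: float) -> tuple[float, float]:
    """Method-of-moments (shape, scale) for a gamma distribution."""
    if mean <= 0:
        raise ValidationError(f"gamma mean must be > 0, got {mean}")
    if se <= 0:
        raise ValidationError(f"gamma se must be > 0, got {se}")
    shape = mean * mean / (se * se)
    scale = se * se / mean
    return shape, scale


def fit_normal(mean: float, se: float) -> tuple[float, float]:
    """(mu, sigma) -- pass-through, the normal is parameterised by its moments."""
    if se <= 0:
        raise ValidationError(f"normal se must be > 0, got {se}")
    return mean, se


def fit_dirichlet(shares, precision: float = 100.0) -> np.ndarray:
    """Concentration vector ``alpha_i = share_i * precision``.

    The mean of the fitted Dirichlet equals ``shares``; ``precision``
    controls the spread (larger = tighter around the shares).
    """
    shares = np.asarray(shares, dtype=float)
    if np.any(shares < 0):
        raise ValidationError("Dirichlet shares must be non-negative")
    if abs(shares.sum() - 1.0) > 1e-9:
        raise ValidationError(
            f"Dirichlet shares must sum to 1, got {shares.sum():.12g}"
        )
    if precision <= 0:
        raise ValidationError("Dirichlet precision must be > 0")
    return shares * precision


@dataclass
class ParameterSpec:
    """One model parameter: point estimate plus distributional assumptions.

    Exactly one of ``se``/``cv`` is given for distributed parameters;
    FIXED parameters carry neither, but may carry a ``range`` so OWSA can
    still vary them.  Dirichlet components additionally name their
    ``dirichlet_group`` -- the group is sampled jointly on the simplex.
    """

    name: str
    point: float
    family: str = "FIXED"
    se: float | None = None
    cv: float | None = None
    range: tuple[float, float] | None = None
    sa_eligible: bool = True
    dirichlet_group: str | None = None
    dirichlet_precision: float = 100.0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValidationError(
                f"parameter {self.name!r}: unknown family {self.family!r}"
            )
        if self.family == "FIXED":
            if self.se is not None or self.cv is not None:
                raise ValidationError(
                    f"parameter {self.name!r}: FIXED parameters take no se/cv"
                )
        elif self.family == "DIRICHLET":
            if self.dirichlet_group is None:
                raise ValidationError(
                    f"parameter {self.name!r}: DIRICHLET needs a dirichlet_group"
                )
        else:
            if (self.se is None) == (self.cv is None):
                raise ValidationError(
                    f"parameter {self.name!r}: give exactly one of se/cv"
                )
        if self.family == "BETA" and not 0.0 < self.point < 1.0:
            raise ValidationError(
                f"parameter {self.name!r}: beta point must lie in (0,1), "
                f"got {self.point}"
            )
        if self.family == "GAMMA" and self.point <= 0:
            raise ValidationError(
                f"parameter {self.name!r}: gamma point must be > 0, "
                f"got {self.point}"
            )
        if self.range is not None:
            lo, hi = self.range
            if not lo <= self.point <= hi:
                raise ValidationError(
                    f"parameter {self.name!r}: range {self.range} does not "
                    f"bracket the point {self.point}"
                )

    # ------------------------------------------------------------------
    @property
    def distributed(self) -> bool:
        return self.family != "FIXED"

    @property
    def se_value(self) -> float | None:
        if self.se is not None:
            return self.se
        if self.cv is not None:
            return se_from_cv(self.point, self.cv)
        return None

    def frozen(self):
        """The fitted scipy distribution (not defined for FIXED/DIRICHLET)."""
        se = self.se_value
        if self.family == "BETA":
            a, b = fit_beta(self.point, se)
            return stats.beta(a, b)
        if self.family == "GAMMA":
            shape, scale = fit_gamma(self.point, se)
            return stats.gamma(shape, scale=scale)
        if self.family == "NORMAL":
            mu, sigma = fit_normal(self.point, se)
            return stats.norm(mu, sigma)
        raise ValidationError(
            f"parameter {self.name!r}: no univariate distribution for "
            f"family {self.family}"
        )

    def ci95(self) -> tuple[float, float]:
        """95% interval: distribution percentiles, or the OWSA range for FIXED."""
        if self.family == "FIXED":
            if self.range is None:
                raise ValidationError(
                    f"parameter {self.name!r}: FIXED without a range has no CI"
                )
            return tuple(self.range)
        if self.family == "DIRICHLET":
            # marginal of a Dirichlet component is beta(alpha_i, alpha_0 - alpha_i)
            a_i = self.point * self.dirichlet_precision
            a_rest = (1.0 - self.point) * self.dirichlet_precision
            d = stats.beta(a_i, a_rest)
            return float(d.ppf(0.025)), float(d.ppf(0.975))
        d = self.frozen()
        return float(d.ppf(0.025)), float(d.ppf(0.975))

    def sample(self, rng: np.random.Generator) -> float:
        """One draw (FIXED returns the point estimate; Dirichlet components
        should be drawn jointly via the registry, this draws the beta marginal)."""
        if self.family == "FIXED":
            return self.point
        if self.family == "DIRICHLET":
            a_i = self.point * self.dirichlet_precision
            a_rest = (1.0 - self.point) * self.dirichlet_precision
            return float(rng.beta(a_i, a_rest))
        if self.family == "NORMAL":
            mu, sigma = fit_normal(self.point, self.se_value)
            x = rng.normal(mu, sigma)
            while x < 0:  # unit costs cannot be negative
                x = rng.normal(mu, sigma)
            return float(x)
        d = self.frozen()
        return float(d.rvs(random_state=rng))


def ci95(spec: ParameterSpec) -> tuple[float, float]:
    """Module-level convenience wrapper around :meth:`ParameterSpec.ci95`."""
    return spec.ci95()


def sample(spec: ParameterSpec, rng: np.random.Generator) -> float:
    """Module-level convenience wrapper around :meth:`ParameterSpec.sample`."""
    return spec.sample(rng)


REGISTRY_COLUMNS = [
    "name", "point", "family", "se", "cv", "range_low", "range_high",
    "sa_eligible", "dirichlet_group", "dirichlet_precision",
]


class ParameterRegistry:
    """Ordered collection of :class:`ParameterSpec`, the single source of
    every number entering the model.

    Dirichlet groups are validated (components sum to one) and sampled
    jointly.  Normal draws are truncated at zero by resampling; the number
    of resampled draws is tracked on ``n_resampled`` for audit.
    """

    def __init__(self, specs):
        self.specs: dict[str, ParameterSpec] = {}
        for s in specs:
            if s.name in self.specs:
                raise ValidationError(f"duplicate parameter name {s.name!r}")
            self.specs[s.name] = s
        self.n_resampled = 0
        self.validate()

    # -- container protocol -------------------------------------------
    def __len__(self):
        return len(self.specs)

    def __iter__(self):
        return iter(self.specs.values())

    def __contains__(self, name):
        return name in self.specs

    def __getitem__(self, name) -> ParameterSpec:
        try:
            return self.specs[name]
        except KeyError:
            raise KeyError(f"unknown parameter {name!r}") from None

    # ------------------------------------------------------------------
    @property
    def counts(self) -> tuple[int, int, int]:
        """(total, distributed, fixed)."""
        dist = sum(1 for s in self if s.distributed)
        return len(self.specs), dist, len(self.specs) - dist

    def validate(self):
        groups: dict[str, float] = {}
        for s in self:
            if s.family == "DIRICHLET":
                groups[s.dirichlet_group] = groups.get(s.dirichlet_group, 0.0) + s.point
        for g, total in groups.items():
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(
                    f"Dirichlet group {g!r} shares sum to {total:.12g}, not 1"
                )

    def dirichlet_groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for s in self:
            if s.family == "DIRICHLET":
                out.setdefault(s.dirichlet_group, []).append(s.name)
        return out

    def point_values(self) -> dict[str, float]:
        return {s.name: s.point for s in self}

    # -- sampling ------------------------------------------------------
    def sample_all(self, rng: np.random.Generator) -> dict[str, float]:
        """One joint draw of every parameter (FIXED at the point estimate)."""
        draws = self.sample_matrix(1, rng)
        return {name: float(col[0]) for name, col in draws.items()}

    def sample_matrix(self, n: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
        """``n`` joint draws, vectorised by family; returns name -> (n,) array.

        Drawing order is deterministic given the registry ordering, so the
        same seed reproduces the same matrix bitwise.
        """
        out: dict[str, np.ndarray] = {}
        group_names = self.dirichlet_groups()
        for s in self:
            if s.family == "FIXED":
                out[s.name] = np.full(n, s.point)
        for s in self:
            if s.family == "BETA":
                a, b = fit_beta(s.point, s.se_value)
                out[s.name] = rng.beta(a, b, size=n)
            elif s.family == "GAMMA":
                shape, scale = fit_gamma(s.point, s.se_value)
                out[s.name] = rng.gamma(shape, scale, size=n)
            elif s.family == "NORMAL":
                mu, sigma = fit_normal(s.point, s.se_value)
                x = rng.normal(mu, sigma, size=n)
                neg = x < 0
                while neg.any():
                    self.n_resampled += int(neg.sum())
                    x[neg] = rng.normal(mu, sigma, size=int(neg.sum()))
                    neg = x < 0
                out[s.name] = x
        for group, names in group_names.items():
            specs = [self[nm] for nm in names]
            alpha = fit_dirichlet([sp.point for sp in specs],
                                  specs[0].dirichlet_precision)
            draws = rng.dirichlet(alpha, size=n)
            for j, nm in enumerate(names):
                out[nm] = draws[:, j]
        return out

    # -- serialisation -------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self:
            rows.append({
                "name": s.name,
                "point": s.point,
                "family": s.family,
                "se": s.se,
                "cv": s.cv,
                "range_low": None if s.range is None else s.range[0],
                "range_high": None if s.range is None else s.range[1],
                "sa_eligible": s.sa_eligible,
                "dirichlet_group": s.dirichlet_group,
                "dirichlet_precision": s.dirichlet_precision,
            })
        return pd.DataFrame(rows, columns=REGISTRY_COLUMNS)

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ParameterRegistry":
        missing = [c for c in REGISTRY_COLUMNS if c not in df.columns
                   and c not in ("dirichlet_precision",)]
        if missing:
            raise ValidationError(f"registry table missing columns: {missing}")
        specs = []
        for _, row in df.iterrows():
            rng_lo, rng_hi = row.get("range_low"), row.get("range_high")
            has_range = pd.notna(rng_lo) and pd.notna(rng_hi)
            specs.append(ParameterSpec(
                name=str(row["name"]),
                point=float(row["point"]),
                family=str(row["family"]),
                se=None if pd.isna(row.get("se")) else float(row["se"]),
                cv=None if pd.isna(row.get("cv")) else float(row["cv"]),
                range=(float(rng_lo), float(rng_hi)) if has_range else None,
                sa_eligible=bool(row["sa_eligible"]),
                dirichlet_group=(None if pd.isna(row.get("dirichlet_group"))
                                 else str(row["dirichlet_group"])),
                dirichlet_precision=(100.0 if pd.isna(row.get("dirichlet_precision"))
                                     else float(row["dirichlet_precision"])),
            ))
        return cls(specs)

    @classmethod
    def from_csv(cls, path) -> "ParameterRegistry":
        return cls.from_frame(pd.read_csv(path))

    def with_overrides(self, overrides: dict[str, float]) -> dict[str, float]:
        """Point values with named overrides applied (names must exist)."""
        values = self.point_values()
        for name, val in overrides.items():
            if name not in values:
                raise KeyError(f"unknown parameter {name!r}")
            values[name] = float(val)
        return values
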