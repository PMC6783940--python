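"""Multi-level full factorial designs and coded model matrices.

A screen crosses every concentration level of every soluble factor
(e.g. FGF2, TGFβ1, CHIR99021 at three levels each, a 3x3x3 = 27-run
design).  For response-surface regression each concentration is mapped
to a coded level on [-1, +1]; the full quadratic model matrix then
carries an intercept, the three linear terms, their squares and all
two-way interactions -- ten columns in total.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Factor",
    "FactorialDesign",
    "build_design",
    "code_levels",
    "quadratic_terms",
    "DesignError",
]


class DesignError(ValueError):
    """Raised for invalid factor or design configuration."""


@dataclass(frozen=True)
class Factor:
    """A controllable culture input with ordered concentration levels.

    Parameters
    ----------
    name : str
        Short identifier, e.g. ``"FGF2"``.
    unit : str
        Concentration unit, e.g. ``"ng/mL"`` or ``"uM"``.
    levels : tuple of float
        Strictly increasing concentrations; the first must be zero
        (the no-addition condition).
    """

    name: str
    unit: str
    levels: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.name:
            raise DesignError("factor name must be non-empty")
        if not self.unit:
            raise DesignError(f"factor {self.name!r}: unit must be non-empty")
        levels = tuple(float(x) for x in self.levels)
        object.__setattr__(self, "levels", levels)
        if len(levels) < 2:
            raise DesignError(f"factor {self.name!r}: needs >=2 levels")
        if any(b <= a for a, b in zip(levels, levels[1:])):
            raise DesignError(f"factor {self.name!r}: levels must be strictly increasing")
        if levels[0] != 0.0:
            raise DesignError(f"factor {self.name!r}: first level must be 0")
        if sum(1 for x in levels if x == 0.0) != 1:
            raise DesignError(f"factor {self.name!r}: exactly one zero level allowed")

    def level_index(self, concentration: float) -> int:
        """Index of *concentration* among the declared levels."""
        for i, lv in enumerate(self.levels):
            if np.isclose(concentration, lv, rtol=0, atol=1e-12):
                return i
        raise DesignError(
            f"concentration {concentration} is not a declared level of factor {self.name!r}"
        )


@dataclass
class FactorialDesign:
    """A full factorial run table.

    ``runs`` has one row per distinct condition with columns ``sample``
    plus one concentration column per factor.  ``replicate_counts`` maps
    sample labels to the number of biological replicates (observations);
    unlisted samples default to one.
    """

    factors: list[Factor]
    runs: pd.DataFrame
    replicate_counts: dict[str, int] = field(default_factory=dict)
    block_size: int | None = None

    @property
    def factor_names(self) -> list[str]:
        return [f.name for f in self.factors]

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    @property
    def blocks(self) -> list[list[str]] | None:
        """Partition of sample labels into consecutive equal-size blocks."""
        if self.block_size is None:
            return None
        labels = list(self.runs["sample"])
        return [
            labels[i : i + self.block_size]
            for i in range(0, len(labels), self.block_size)
        ]

    def observations(self) -> pd.DataFrame:
        """One row per observation, expanding replicated samples.

        Replicates of a sample keep the sample label and get an
        ``observation`` label suffixed ``-r2``, ``-r3``, ...; the first
        replicate keeps the bare label.
        """
        rows = []
        for _, run in self.runs.iterrows():
            n_rep = int(self.replicate_counts.get(run["sample"], 1))
            for r in range(1, n_rep + 1):
                obs = run["sample"] if r == 1 else f"{run['sample']}-r{r}"
                row = {"observation": obs, "sample": run["sample"]}
                for name in self.factor_names:
                    row[name] = run[name]
                rows.append(row)
        return pd.DataFrame(rows)

    def n_observations(self) -> int:
        return sum(int(self.replicate_counts.get(s, 1)) for s in self.runs["sample"])


def build_design(
    factors: list[Factor],
    replicate_counts: dict[str, int] | None = None,
    block_size: int | None = None,
    sample_prefix: str = "Sample ",
) -> FactorialDesign:
    """Construct the full cross-product of factor levels.

    Runs are ordered lexicographically by level index with the first
    factor varying slowest and the last factor varying fastest, and are
    labelled ``"Sample 1"``, ``"Sample 2"``, ... in that order.
    """
    if not factors:
        raise DesignError("at least one factor required")
    names = [f.name for f in factors]
    if len(set(names)) != len(names):
        raise DesignError(f"duplicate factor names in {names}")
    combos = list(itertools.product(*(f.levels for f in factors)))
    if block_size is not None and len(combos) % block_size != 0:
        raise DesignError(
            f"block_size {block_size} does not divide run count {len(combos)}"
        )
    runs = pd.DataFrame(combos, columns=names)
    runs.insert(0, "sample", [f"{sample_prefix}{i + 1}" for i in range(len(combos))])
    replicate_counts = dict(replicate_counts or {})
    for label, count in replicate_counts.items():
        if label not in set(runs["sample"]):
            raise DesignError(f"replicate_counts references unknown sample {label!r}")
        if int(count) < 1:
            raise DesignError(f"replicate count for {label!r} must be positive")
    return FactorialDesign(
        factors=list(factors),
        runs=runs,
        replicate_counts=replicate_counts,
        block_size=block_size,
    )


def _coded_linear(factor: Factor, concentrations: np.ndarray, scheme: str) -> np.ndarray:
    """Map concentrations of one factor to centered/scaled coded levels."""
    if scheme == "nominal":
        # level index -> nominal input fraction, then 2(f - 1/2).  The
        # three-level screen frames its doses as 0, 1/3 and 1 of the full
        # input, so the mid level codes to -1/3 rather than 0.
        k = len(factor.levels)
        fractions = (0.0, 1.0 / 3.0, 1.0) if k == 3 else tuple(
            i / (k - 1) for i in range(k)
        )
        idx = [factor.level_index(c) for c in concentrations]
        frac = np.array([fractions[i] for i in idx])
    elif scheme == "concentration":
        frac = np.asarray(concentrations, dtype=float) / factor.levels[-1]
    else:
        raise DesignError(f"unknown coding scheme {scheme!r}")
    return 2.0 * (frac - 0.5)


def quadratic_terms(factor_names: list[str]) -> list[str]:
    """Column names of the full quadratic model in canonical order."""
    cols = ["intercept"]
    cols += [f"{n}" for n in factor_names]
    cols += [f"{n}^2" for n in factor_names]
    cols += [
        f"{a}:{b}" for a, b in itertools.combinations(factor_names, 2)
    ]
    return cols


def code_levels(
    design: FactorialDesign,
    scheme: str = "nominal",
    orthogonal: bool = False,
) -> pd.DataFrame:
    """Build the coded full-quadratic model matrix, one row per observation.

    Parameters
    ----------
    design : FactorialDesign
    scheme : {"nominal", "concentration"}
        ``"nominal"`` codes by level index: level i of k maps to fraction
        f = i/(k-1) and then X = 2(f - 1/2), giving {-1, -1/3, +1} for a
        3-level factor regardless of the true concentration spacing.
        ``"concentration"`` uses f = c/c_max instead.
    orthogonal : bool
        If true, replace each factor's linear/quadratic pair by
        orthogonal polynomial contrasts (Gram-Schmidt of [1, X, X^2]
        over the observation rows); interactions are products of the
        orthogonalized linear columns.

    Returns
    -------
    pandas.DataFrame
        Indexed by observation label with the ten canonical columns
        (for three factors): intercept, linear, quadratic, interactions.
    """
    obs = design.observations()
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(obs))}
    linear: dict[str, np.ndarray] = {}
    for f in design.factors:
        x = _coded_linear(f, obs[f.name].to_numpy(), scheme)
        linear[f.name] = x
        cols[f.name] = x
        cols[f"{f.name}^2"] = x * x
    if orthogonal:
        for f in design.factors:
            x = linear[f.name]
            one = np.ones_like(x)
            lin = x - x.mean()
            q = x * x
            # project out intercept and linear component
            q = q - q.mean() - (q @ lin) / (lin @ lin) * lin
            linear[f.name] = lin
            cols[f.name] = lin
            cols[f"{f.name}^2"] = q
    for a, b in itertools.combinations(design.factor_names, 2):
        cols[f"{a}:{b}"] = linear[a] * linear[b]
    X = pd.DataFrame(cols, index=obs["observation"])
    return X[quadratic_terms(design.factor_names)]


def table1_factors() -> list[Factor]:
    """The three-pathway activator factors of the reference screen.

    FGF2 activates FGF signaling, TGFβ1 activates TGFβ/Nodal signaling
    and CHIR99021 (a GSK3β inhibitor) activates canonical Wnt signaling.
    """
    return [
        Factor("FGF2", "ng/mL", (0.0, 35.0, 100.0)),
        Factor("TGFb", "ng/mL", (0.0, 0.7, 2.0)),
        Factor("CHIR", "uM", (0.0, 2.0, 6.0)),
    ]


def table1_design(e6_replicates: int = 3) -> FactorialDesign:
    """The 27-condition screen design with the basal-medium condition replicated.

    Sample 1 (the zero-everything E6 condition) is run in biological
    triplicate by default, giving 29 observations and 28 total degrees
    of freedom.
    """
    return build_design(
        table1_factors(),
        replicate_counts={"Sample 1": e6_replicates},
        block_size=9,
    )
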