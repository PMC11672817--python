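"""Design assembly and mixed-model equations for the repeatability animal model.

The model is  y = X b + Z u + W pe + e  with
u ~ N(0, A sigma_u2), pe ~ N(0, I sigma_pe2), e ~ N(0, I sigma_e2):
fixed effects are the HYS contemporary group (one-hot, absorbing the
intercept), parity (drop-first contrasts) and two centred linear covariates
(age at calving, days in milk at first insemination); u spans every animal
in the pedigree and pe one level per phenotyped cow.

`solve_mme` solves Henderson's mixed-model equations at given variance
components; it is the deterministic BLUP counterpart of the Gibbs samplers
and serves as their oracle when the variances are held fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .pedigree import Pedigree, build_A_inverse, inbreeding


class DesignError(ValueError):
    pass


@dataclass
class VarianceComponents:
    """Additive genetic, permanent-environment and residual variances (days^2)."""

    sigma_u2: float
    sigma_pe2: float
    sigma_e2: float

    def validate(self):
        if min(self.sigma_u2, self.sigma_pe2, self.sigma_e2) <= 0:
            raise ValueError("variance components must be strictly positive")

    @property
    def total(self) -> float:
        return self.sigma_u2 + self.sigma_pe2 + self.sigma_e2


def heritability(vc) -> float:
    """h2 = sigma_u2 / (sigma_u2 + sigma_pe2 + sigma_e2).

    Accepts a :class:`VarianceComponents` or a (u, pe, e) triple.
    """
    if not isinstance(vc, VarianceComponents):
        vc = VarianceComponents(*vc)
    total = vc.total
    if total <= 0:
        raise ValueError("non-positive total variance")
    return vc.sigma_u2 / total


@dataclass
class DesignSystem:
    """Incidence structure of one trait's animal model.

    ``T = [X Z W]`` stacked horizontally (CSR); slices locate each block in
    the effect vector.  ``cow_internal`` maps each pe level to its pedigree
    id so EBVs and pe solutions can be reported per animal.
    """

    T: sparse.csr_matrix
    y: np.ndarray
    n_fixed: int
    n_animals: int
    n_cows: int
    fixed_names: list
    hys_levels: list
    parity_levels: list
    cow_internal: np.ndarray  # internal pedigree id per pe level
    Ainv: sparse.csr_matrix
    record_cow_level: np.ndarray  # pe level index per record
    covariate_means: dict = field(default_factory=dict)

    @property
    def n_effects(self) -> int:
        return self.n_fixed + self.n_animals + self.n_cows

    @property
    def slices(self):
        p, q, c = self.n_fixed, self.n_animals, self.n_cows
        return {
            "fixed": slice(0, p),
            "u": slice(p, p + q),
            "pe": slice(p + q, p + q + c),
        }


def build_design(
    records: pd.DataFrame,
    ped: Pedigree,
    response: str = "do",
    Ainv: sparse.csr_matrix | None = None,
) -> DesignSystem:
    """Assemble X, Z, W incidence matrices from edited records.

    Records must carry ``hys``, ``parity``, ``age_at_calving``,
    ``dim_first_ai`` and the response column; every ``cow_id`` must be in
    the pedigree.  Covariates are centred so their slopes are decorrelated
    from the HYS means.
    """
    if "hys" not in records.columns:
        raise DesignError("records need a 'hys' column (run edit_records first)")
    missing = [c for c in records["cow_id"] if c not in ped.id_map]
    if missing:
        raise DesignError(f"cows missing from pedigree: {sorted(set(missing))[:10]}")

    n = len(records)
    hys_levels = sorted(records["hys"].unique())
    parity_levels = sorted(records["parity"].unique())
    hys_idx = {h: k for k, h in enumerate(hys_levels)}
    par_idx = {p: k for k, p in enumerate(parity_levels)}

    rows, cols, vals = [], [], []
    fixed_names = [f"hys:{h}" for h in hys_levels]
    # HYS one-hot absorbs the intercept
    for r, h in enumerate(records["hys"]):
        rows.append(r), cols.append(hys_idx[h]), vals.append(1.0)
    off = len(hys_levels)
    # parity: drop-first contrasts
    for p in parity_levels[1:]:
        fixed_names.append(f"parity:{p}")
    for r, p in enumerate(records["parity"]):
        k = par_idx[p]
        if k > 0:
            rows.append(r), cols.append(off + k - 1), vals.append(1.0)
    off += len(parity_levels) - 1
    cov_means = {}
    for cov in ("age_at_calving", "dim_first_ai"):
        fixed_names.append(f"cov:{cov}")
        mu = float(records[cov].mean())
        cov_means[cov] = mu
        x = records[cov].to_numpy(dtype=float) - mu
        rows.extend(range(n)), cols.extend([off] * n), vals.extend(x)
        off += 1
    n_fixed = off
    X = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n_fixed))

    animal_internal = ped.to_internal(records["cow_id"].tolist())
    Z = sparse.coo_matrix(
        (np.ones(n), (np.arange(n), animal_internal - 1)), shape=(n, ped.n)
    )
    cow_ids, cow_level = np.unique(animal_internal, return_inverse=True)
    W = sparse.coo_matrix(
        (np.ones(n), (np.arange(n), cow_level)), shape=(n, len(cow_ids))
    )
    T = sparse.hstack([X, Z, W]).tocsr()
    if Ainv is None:
        Ainv = build_A_inverse(ped, inbreeding(ped))
    y = records[response].to_numpy(dtype=float) if response in records else np.zeros(n)
    return DesignSystem(
        T=T,
        y=y,
        n_fixed=n_fixed,
        n_animals=ped.n,
        n_cows=len(cow_ids),
        fixed_names=fixed_names,
        hys_levels=hys_levels,
        parity_levels=list(parity_levels),
        cow_internal=cow_ids,
        Ainv=Ainv,
        record_cow_level=cow_level,
        covariate_means=cov_means,
    )


@dataclass
class MMESolution:
    fixed: np.ndarray
    u: np.ndarray
    pe: np.ndarray

    @property
    def stacked(self) -> np.ndarray:
        return np.concatenate([self.fixed, self.u, self.pe])

    def to_frame(self, design: "DesignSystem") -> pd.DataFrame:
        """Long-format solutions: effect_type, level, estimate."""
        rows = (
            [("fixed", name, v) for name, v in zip(design.fixed_names, self.fixed)]
            + [("u", i + 1, v) for i, v in enumerate(self.u)]
            + [("pe", int(c), v) for c, v in zip(design.cow_internal, self.pe)]
        )
        return pd.DataFrame(rows, columns=["effect_type", "level", "estimate"])


def mme_coefficient_matrix(
    design: DesignSystem, vc: VarianceComponents
) -> sparse.csr_matrix:
    """Henderson's coefficient matrix T'T + diag-block(0, Ainv*k_u, I*k_pe)."""
    vc.validate()
    k_u = vc.sigma_e2 / vc.sigma_u2
    k_pe = vc.sigma_e2 / vc.sigma_pe2
    M = (design.T.T @ design.T).tocsr()
    blocks = sparse.block_diag(
        [
            sparse.csr_matrix((design.n_fixed, design.n_fixed)),
            design.Ainv * k_u,
            sparse.identity(design.n_cows) * k_pe,
        ]
    )
    return (M + blocks).tocsr()


def solve_mme(
    design: DesignSystem, vc: VarianceComponents, y: np.ndarray | None = None
) -> MMESolution:
    """BLUE/BLUP solutions of the mixed-model equations at fixed variances."""
    y = design.y if y is None else np.asarray(y, dtype=float)
    C = mme_coefficient_matrix(design, vc)
    rhs = design.T.T @ y
    theta = spsolve(C.tocsc(), rhs)
    resid = C @ theta - rhs
    denom = max(1.0, float(np.linalg.norm(rhs)))
    if np.linalg.norm(resid) / denom > 1e-6:
        raise DesignError(
            "mixed-model equations are (near-)singular; "
            "check fixed-effect identifiability"
        )
    s = design.slices
    return MMESolution(fixed=theta[s["fixed"]], u=theta[s["u"]], pe=theta[s["pe"]])
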