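"""Recursive path models over observed variables.

For a recursive (acyclic) system with uncorrelated errors, equation-wise
least squares is the maximum-likelihood solution; the covariance machinery
is used only for the discrepancy statistic, fit indices and information
criteria. All variables are standardized internally, so reported
coefficients are standardized path coefficients (beta).

Model-implied covariance: ``Sigma(theta) = (I - B)^-1 Psi (I - B)^-T`` with
``B`` the coefficient matrix and ``Psi`` holding residual variances for
endogenous variables and the saturated sample covariance block for
exogenous ones. Discrepancy: ``T = (n - 1) F_ML`` with
``F_ML = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

RESPONSE = "lnS"
PREDICTORS = ("temperature", "precipitation", "npp", "age", "dr")
MEDIATORS = ("npp", "age", "dr")


# ---------------------------------------------------------------------------
# variable preparation
# ---------------------------------------------------------------------------

@dataclass
class VariableTable:
    """Per-cell modeling table: lnS plus z-scored predictors.

    ``data`` holds one row per retained cell; all columns are z-scored
    (including lnS, so path coefficients are standardized). ``n_dropped``
    counts cells removed for zero richness or missing age / rate.
    """

    data: pd.DataFrame
    n_dropped: int = 0

    @property
    def n(self) -> int:
        return len(self.data)


def prepare_variables(richness: pd.Series, env, ages: pd.Series,
                      rates: pd.Series, min_cells: int = 30,
                      include_coords: bool = False) -> VariableTable:
    """Assemble and standardize the modeling table.

    Cells with zero richness or missing age / rate are dropped (their count
    is reported); richness is natural-log transformed before z-scoring.
    """
    env_df = env.data if hasattr(env, "data") else env
    df = pd.DataFrame({
        "richness": richness,
        "temperature": env_df["temperature"],
        "precipitation": env_df["precipitation"],
        "npp": env_df["npp"],
        "age": ages,
        "dr": rates,
    })
    if include_coords:
        for c in ("lat", "lon"):
            if c not in env_df.columns:
                raise ValueError(f"include_coords requires column {c!r}")
            df[c] = env_df[c]
    ok = (df["richness"] >= 1) & df.notna().all(axis=1)
    n_dropped = int((~ok).sum())
    df = df[ok]
    if len(df) < min_cells:
        raise ValueError(f"insufficient cells after filtering: {len(df)} < {min_cells}")
    out = pd.DataFrame(index=df.index)
    out[RESPONSE] = np.log(df["richness"].astype(float))
    for c in df.columns.drop("richness"):
        out[c] = df[c].astype(float)
    z = (out - out.mean()) / out.std(ddof=1)
    if z.isna().any().any():
        bad = z.columns[z.isna().any()].tolist()
        raise ValueError(f"constant columns cannot be z-scored: {bad}")
    return VariableTable(z, n_dropped)


# ---------------------------------------------------------------------------
# model graphs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PathModel:
    """A DAG over observed variables; edges are (parent, child) pairs."""

    variables: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]

    def __post_init__(self):
        vs = set(self.variables)
        for a, b in self.edges:
            if a not in vs or b not in vs:
                raise ValueError(f"edge ({a},{b}) uses unknown variable")
        self.topological_order()  # raises on cycles

    @property
    def endogenous(self) -> tuple[str, ...]:
        kids = {b for _, b in self.edges}
        return tuple(v for v in self.variables if v in kids)

    @property
    def exogenous(self) -> tuple[str, ...]:
        kids = {b for _, b in self.edges}
        return tuple(v for v in self.variables if v not in kids)

    def parents(self, v: str) -> tuple[str, ...]:
        return tuple(a for a, b in self.edges if b == v)

    def children(self, v: str) -> tuple[str, ...]:
        return tuple(b for a, b in self.edges if a == v)

    def topological_order(self) -> list[str]:
        indeg = {v: 0 for v in self.variables}
        for _, b in self.edges:
            indeg[b] += 1
        queue = [v for v in self.variables if indeg[v] == 0]
        order = []
        while queue:
            v = queue.pop(0)
            order.append(v)
            for c in self.children(v):
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        if len(order) != len(self.variables):
            raise ValueError("path model contains a cycle")
        return order

    def n_free_parameters(self) -> int:
        """Free betas + endogenous residual variances + exogenous (co)variances."""
        nexo = len(self.exogenous)
        return len(self.edges) + len(self.endogenous) + nexo + nexo * (nexo - 1) // 2

    def with_spatial_covariates(self) -> "PathModel":
        """Latitude/longitude added as exogenous parents of every endogenous variable."""
        new_vars = tuple(v for v in ("lat", "lon") if v not in self.variables)
        extra = tuple((c, v) for c in ("lat", "lon") for v in self.endogenous)
        return PathModel(self.variables + new_vars, self.edges + extra)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    model: PathModel
    beta: pd.DataFrame          # child x parent standardized coefficients
    psi: np.ndarray             # error variances / exogenous covariances
    sigma: np.ndarray           # implied covariance, variable order = model.variables
    sample_cov: np.ndarray
    r2: dict[str, float]
    loglik: float
    discrepancy: float          # T = (n - 1) F_ML
    df: int
    cfi: float
    tli: float
    rmsea: float
    srmr: float
    aic: float
    bic: float
    n: int
    residuals: dict[str, np.ndarray] = field(default_factory=dict)

    def coefficient(self, parent: str, child: str) -> float:
        return float(self.beta.loc[child, parent])

    def to_dict(self) -> dict:
        return {
            "edges": {f"{a}->{b}": self.coefficient(a, b) for a, b in self.model.edges},
            "r2": self.r2, "loglik": self.loglik, "T": self.discrepancy,
            "df": self.df, "cfi": self.cfi, "tli": self.tli,
            "rmsea": self.rmsea, "srmr": self.srmr,
            "aic": self.aic, "bic": self.bic, "n": self.n,
        }


def fit_path_model(model: PathModel, table) -> FitResult:
    """ML fit of a recursive path model (equation-wise least squares).

    ``table`` is a ``VariableTable`` or a DataFrame whose columns cover the
    model variables. Raises on singular (collinear) parent sets.
    """
    df = table.data if isinstance(table, VariableTable) else table
    missing = set(model.variables) - set(df.columns)
    if missing:
        raise ValueError(f"table lacks model variables: {sorted(missing)}")
    X = df[list(model.variables)].to_numpy(dtype=float)
    n, p = X.shape
    S = np.cov(X, rowvar=False, ddof=1)
    vs = list(model.variables)
    pos = {v: i for i, v in enumerate(vs)}
    B = np.zeros((p, p))
    Psi = np.zeros((p, p))
    r2: dict[str, float] = {}
    residuals: dict[str, np.ndarray] = {}
    for v in model.endogenous:
        pa = model.parents(v)
        ip = [pos[a] for a in pa]
        iv = pos[v]
        Sxx = S[np.ix_(ip, ip)]
        if np.linalg.cond(Sxx) > 1e10:
            raise ValueError(f"collinear parents for {v!r}: {pa}")
        b = np.linalg.solve(Sxx, S[ip, iv])
        B[iv, ip] = b
        resid_var = S[iv, iv] - S[iv, ip] @ b
        Psi[iv, iv] = max(resid_var, 1e-12)
        r2[v] = float(1.0 - resid_var / S[iv, iv])
        residuals[v] = X[:, iv] - X[:, ip] @ b
    exo = [pos[v] for v in model.exogenous]
    Psi[np.ix_(exo, exo)] = S[np.ix_(exo, exo)]
    inv = np.linalg.inv(np.eye(p) - B)
    Sigma = inv @ Psi @ inv.T
    sign_S, logdet_S = np.linalg.slogdet(S)
    sign_M, logdet_M = np.linalg.slogdet(Sigma)
    if sign_S <= 0 or sign_M <= 0:
        raise ValueError("covariance matrix not positive definite")
    f_ml = logdet_M + float(np.trace(S @ np.linalg.inv(Sigma))) - logdet_S - p
    f_ml = max(f_ml, 0.0)
    T = (n - 1) * f_ml
    q = model.n_free_parameters()
    dof = p * (p + 1) // 2 - q
    loglik = -0.5 * n * (p * math.log(2 * math.pi) + logdet_M
                         + float(np.trace(S @ np.linalg.inv(Sigma))))
    Tb, dfb = _baseline(S, n)
    if dof == 0:  # saturated: Sigma == S by construction
        idx = {"cfi": 1.0, "tli": 1.0, "rmsea": 0.0}
    else:
        idx = fit_indices(T, dof, Tb, dfb, n)
    aic, bic = information_criteria(loglik, q, n)
    return FitResult(
        model=model,
        beta=pd.DataFrame(B, index=vs, columns=vs),
        psi=Psi, sigma=Sigma, sample_cov=S, r2=r2, loglik=loglik,
        discrepancy=T, df=dof,
        cfi=idx["cfi"], tli=idx["tli"], rmsea=idx["rmsea"],
        srmr=_srmr(S, Sigma), aic=aic, bic=bic, n=n, residuals=residuals,
    )


def _baseline(S: np.ndarray, n: int) -> tuple[float, int]:
    """Independence baseline: covariances fixed at 0, variances free."""
    p = S.shape[0]
    Sigma_b = np.diag(np.diag(S))
    _, logdet_S = np.linalg.slogdet(S)
    _, logdet_b = np.linalg.slogdet(Sigma_b)
    f_b = logdet_b + float(np.trace(S @ np.linalg.inv(Sigma_b))) - logdet_S - p
    return (n - 1) * max(f_b, 0.0), p * (p + 1) // 2 - p


def fit_indices(T: float, df: int, T_baseline: float, df_baseline: int,
                n: int) -> dict[str, float]:
    """CFI, TLI and RMSEA from discrepancy statistics.

    Flags (NaN) the incremental indices when the baseline fits no worse than
    its degrees of freedom.
    """
    if df <= 0 or df_baseline <= 0:
        raise ValueError("df and df_baseline must be positive")
    if T_baseline <= df_baseline:
        cfi = tli = float("nan")
    else:
        num = max(T - df, 0.0)
        den = max(T_baseline - df_baseline, T - df, 0.0)
        cfi = 1.0 - (num / den if den > 0 else 0.0)
        ratio_b = T_baseline / df_baseline
        tli = (ratio_b - T / df) / (ratio_b - 1.0)
    rmsea = math.sqrt(max(T - df, 0.0) / (df * (n - 1)))
    return {"cfi": cfi, "tli": tli, "rmsea": rmsea}


def _srmr(S: np.ndarray, Sigma: np.ndarray) -> float:
    p = S.shape[0]
    sd = np.sqrt(np.diag(S))
    resid = (S - Sigma) / np.outer(sd, sd)
    iu = np.triu_indices(p)
    return float(np.sqrt(np.mean(resid[iu] ** 2)))


def information_criteria(loglik: float, q: int, n: int) -> tuple[float, float]:
    """AIC = -2 logL + 2q; BIC = -2 logL + q ln n."""
    if q < 1 or n < 2:
        raise ValueError("need q >= 1 and n >= 2")
    return -2.0 * loglik + 2.0 * q, -2.0 * loglik + q * math.log(n)


# ---------------------------------------------------------------------------
# effect decomposition
# ---------------------------------------------------------------------------

@dataclass
class EffectDecomposition:
    """Direct and mediator-classified indirect effects on the response."""

    direct: dict[str, float]
    indirect: dict[str, dict[str, float]]  # predictor -> {mediator: effect}
    total: dict[str, float]


def effect_decomposition(fit: FitResult, model: PathModel | None = None,
                         response: str = RESPONSE,
                         mediators: tuple[str, ...] = MEDIATORS) -> EffectDecomposition:
    """Path-tracing decomposition of standardized effects on ``response``.

    The direct effect is the coefficient of the edge into the response;
    each indirect path is assigned to the class of its last mediator (the
    variable whose edge enters the response), so the classes partition the
    indirect effect exactly and ``total = direct + sum(indirect)``.
    """
    model = model or fit.model
    direct: dict[str, float] = {}
    indirect: dict[str, dict[str, float]] = {}
    total: dict[str, float] = {}
    for pred in model.variables:
        if pred == response:
            continue
        d = 0.0
        cls = {m: 0.0 for m in mediators}
        other = 0.0
        for path, prod in _paths(model, fit, pred, response):
            if len(path) == 2:
                d += prod
            else:
                last = path[-2]
                if last in cls:
                    cls[last] += prod
                else:
                    other += prod
        if other:
            cls = {**cls, "other": other}
        direct[pred] = d
        indirect[pred] = cls
        total[pred] = d + sum(cls.values())
    return EffectDecomposition(direct, indirect, total)


def _paths(model: PathModel, fit: FitResult, src: str, dst: str):
    """All directed paths src -> dst with their coefficient products."""
    out = []

    def walk(v, path, prod):
        if v == dst:
            out.append((tuple(path), prod))
            return
        for c in model.children(v):
            walk(c, path + [c], prod * fit.coefficient(v, c))

    walk(src, [src], 1.0)
    return out


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def vif(table, predictors) -> dict[str, float]:
    """Variance inflation factor per predictor (inf under perfect collinearity)."""
    df = table.data if isinstance(table, VariableTable) else table
    predictors = list(predictors)
    if len(predictors) < 2:
        raise ValueError("need at least two predictors")
    X = df[predictors].to_numpy(dtype=float)
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    out = {}
    for j, name in enumerate(predictors):
        others = np.delete(X, j, axis=1)
        b, *_ = np.linalg.lstsq(others, X[:, j], rcond=None)
        resid = X[:, j] - others @ b
        r2 = 1.0 - resid @ resid / (X[:, j] @ X[:, j])
        out[name] = float("inf") if r2 >= 1.0 - 1e-12 else float(1.0 / (1.0 - r2))
    return out


def spatial_weights(coords: np.ndarray, scheme: str = "knn", k: int = 8) -> np.ndarray:
    """Row-standardized spatial weight matrix.

    ``knn``: k-nearest neighbours on coordinates (default k = 8);
    ``rook``: unit-lattice edge adjacency (|dx| + |dy| == 1).
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if scheme == "knn":
        k = min(k, n - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
        _, idx = nn.kneighbors(coords)
        W = np.zeros((n, n))
        for i in range(n):
            for j in idx[i, 1:]:
                W[i, j] = 1.0
    elif scheme == "rook":
        d = np.abs(coords[:, None, :] - coords[None, :, :]).sum(axis=2)
        W = (np.abs(d - 1.0) < 1e-9).astype(float)
    else:
        raise ValueError(f"unknown weights scheme {scheme!r}")
    rows = W.sum(axis=1, keepdims=True)
    rows[rows == 0] = 1.0
    return W / rows


def morans_i(values, coords, scheme: str = "knn", k: int = 8,
             weights: np.ndarray | None = None) -> float:
    """Moran's I spatial autocorrelation statistic.

    ``I = (n / sum W) * z' W z / z' z`` with centered values ``z``.
    """
    z = np.asarray(values, dtype=float)
    n = len(z)
    if n < 4:
        raise ValueError("need at least 4 locations")
    if np.ptp(z) == 0:
        raise ValueError("zero variance in values")
    W = weights if weights is not None else spatial_weights(coords, scheme, k)
    z = z - z.mean()
    return float(n / W.sum() * (z @ W @ z) / (z @ z))
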