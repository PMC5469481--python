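"""Bayes classification of pairwise relationships from (HGMR, AGMR).

After cutoff-based staging — pairs with AGMR below the identical cutoff
are labelled ID, pairs with HGMR above the unrelated cutoff are labelled
UN — the remaining close pairs are assigned one of PO, FS, D2, D3 by the
posterior over the joint (HGMR, AGMR) density:

* FS, D2, D3: bivariate normal with per-relationship means, SDs and
  correlation rho.
* PO: HGMR is exponential with rate k (homozygous mismatches of a
  parent-offspring pair come only from genotyping error, and the
  observed HGMR distribution decays roughly exponentially), AGMR is
  normal, and the two are taken as independent.

With equal priors the posterior is the normalized density ratio; the
label is the argmax.  Default parameters are the pooled empirical values
from a large genotype repository, stored as fractions (HGMR/AGMR in
[0, 1]); reports print percentages.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import theory
from .metrics import PairStats

log = logging.getLogger(__name__)

__all__ = [
    "BivariateParams",
    "POParams",
    "RelationshipModel",
    "default_model",
    "analytic_model",
    "density",
    "classify_pair",
    "fit_model",
    "decision_boundaries",
    "read_model",
    "write_model",
]

CLOSE_RELATIONSHIPS = ("PO", "FS", "D2", "D3")

K_RATE_CAP = 1e5  # densest admissible exponential for degenerate all-zero PO fits


@dataclass(frozen=True)
class BivariateParams:
    """Bivariate-normal parameters: x = HGMR, y = AGMR (fractions)."""

    mu_x: float
    sd_x: float
    mu_y: float
    sd_y: float
    rho: float

    def __post_init__(self) -> None:
        if self.sd_x <= 0 or self.sd_y <= 0:
            raise ValueError("standard deviations must be positive")
        if not -1.0 < self.rho < 1.0:
            raise ValueError("|rho| must be < 1")


@dataclass(frozen=True)
class POParams:
    """Parent-offspring: exponential HGMR (rate k) x normal AGMR, independent."""

    k_rate: float
    mu_y: float
    sd_y: float

    def __post_init__(self) -> None:
        if self.k_rate <= 0:
            raise ValueError("k_rate must be positive")
        if self.sd_y <= 0:
            raise ValueError("sd_y must be positive")


def _default_hgmr_cutoff() -> float:
    """Midpoint of the analytic D3 and UN HGMR expectations (~0.188)."""
    return 0.5 * (
        theory.expected_hgmr(theory.PROFILES["D3"])
        + theory.expected_hgmr(theory.PROFILES["UN"])
    )


@dataclass(frozen=True)
class RelationshipModel:
    po: POParams
    fs: BivariateParams
    d2: BivariateParams
    d3: BivariateParams
    agmr_identical_cutoff: float = 0.20
    hgmr_unrelated_cutoff: float = field(default_factory=_default_hgmr_cutoff)
    priors: dict[str, float] = field(
        default_factory=lambda: {r: 0.25 for r in CLOSE_RELATIONSHIPS}
    )

    def __post_init__(self) -> None:
        total = sum(self.priors.get(r, 0.0) for r in CLOSE_RELATIONSHIPS)
        if not math.isclose(total, 1.0, rel_tol=1e-9):
            object.__setattr__(
                self,
                "priors",
                {r: self.priors.get(r, 0.0) / total for r in CLOSE_RELATIONSHIPS},
            )

    def params(self, rel: str):
        return {"PO": self.po, "FS": self.fs, "D2": self.d2, "D3": self.d3}[rel]


def default_model() -> RelationshipModel:
    """Pooled empirical parameters (percent values stored as fractions).

    The PO exponential rate is 1/mean(PO HGMR) = 1/0.0004 = 2500; the
    classifier is insensitive to k over a wide range because PO pairs are
    far from every other class in (HGMR, AGMR).
    """
    return RelationshipModel(
        po=POParams(k_rate=2500.0, mu_y=0.3948, sd_y=0.0147),
        fs=BivariateParams(0.0486, 0.0102, 0.3359, 0.0232, 0.784),
        d2=BivariateParams(0.1116, 0.0135, 0.4730, 0.0110, 0.803),
        d3=BivariateParams(0.1732, 0.0135, 0.5107, 0.0096, 0.830),
    )


def analytic_model(
    freq: theory.FreqSpec = theory.FreqSpec(),
    S: int = 10_000,
    k_rate: float = 2500.0,
    rho: float = 0.0,
) -> RelationshipModel:
    """Model with analytic means/SDs under an allele-frequency spec.

    Useful when no labelled training pairs exist: means come from the
    closed-form AGMR/HGMR expectations, SDs from the binomial panel-size
    formulas.  The cross-metric correlation is not available in closed
    form and defaults to 0.
    """
    def biv(rel: str) -> BivariateParams:
        prof = theory.PROFILES[rel]
        return BivariateParams(
            mu_x=theory.expected_hgmr(prof, freq),
            sd_x=theory.sd_hgmr(prof, freq, S),
            mu_y=theory.expected_agmr(prof, freq),
            sd_y=theory.sd_agmr(prof, freq, S),
            rho=rho,
        )

    po_prof = theory.PROFILES["PO"]
    return RelationshipModel(
        po=POParams(
            k_rate=k_rate,
            mu_y=theory.expected_agmr(po_prof, freq),
            sd_y=theory.sd_agmr(po_prof, freq, S),
        ),
        fs=biv("FS"),
        d2=biv("D2"),
        d3=biv("D3"),
    )


def density(rel: str, x: float, y: float, model: RelationshipModel) -> float:
    """Joint (HGMR, AGMR) density of relationship ``rel`` at (x, y)."""
    if x is None or y is None:
        raise ValueError("density requires defined HGMR and AGMR values")
    if rel == "PO":
        p = model.po
        norm_y = math.exp(-0.5 * ((y - p.mu_y) / p.sd_y) ** 2) / (
            p.sd_y * math.sqrt(2 * math.pi)
        )
        return p.k_rate * math.exp(-p.k_rate * x) * norm_y
    b: BivariateParams = model.params(rel)
    zx = (x - b.mu_x) / b.sd_x
    zy = (y - b.mu_y) / b.sd_y
    om = 1.0 - b.rho**2
    expo = -(zx * zx - 2 * b.rho * zx * zy + zy * zy) / (2 * om)
    return math.exp(expo) / (2 * math.pi * b.sd_x * b.sd_y * math.sqrt(om))


_TIE_ORDER = {r: i for i, r in enumerate(CLOSE_RELATIONSHIPS)}  # closer wins


def classify_pair(
    stats: PairStats, model: RelationshipModel
) -> tuple[str, dict[str, float] | None]:
    """Label a pair ID / PO / FS / D2 / D3 / UN with posteriors where applicable.

    Stage 1: AGMR below the identical cutoff -> ID.  Stage 2: HGMR above
    the unrelated cutoff -> UN.  Stage 3: posterior over {PO, FS, D2, D3}
    proportional to prior x density; ties broken toward the closer
    relationship.
    """
    agmr = stats.agmr
    if agmr is None:
        raise ValueError(f"pair {stats.id_a}/{stats.id_b} has no compared SNPs")
    if agmr < model.agmr_identical_cutoff:
        return "ID", None
    hgmr = stats.hgmr
    if hgmr is None:
        log.warning(
            "pair %s/%s: HGMR undefined (no doubly homozygous SNPs); labelling UN",
            stats.id_a,
            stats.id_b,
        )
        return "UN", None
    if hgmr > model.hgmr_unrelated_cutoff:
        return "UN", None
    weighted = {
        r: model.priors[r] * density(r, hgmr, agmr, model)
        for r in CLOSE_RELATIONSHIPS
    }
    total = sum(weighted.values())
    if total == 0.0:
        # all densities underflow; fall back to nearest class in z-units of AGMR
        log.warning("pair %s/%s: joint density underflow", stats.id_a, stats.id_b)
        posteriors = {r: 1.0 / len(weighted) for r in weighted}
    else:
        posteriors = {r: w / total for r, w in weighted.items()}
    label = max(posteriors, key=lambda r: (posteriors[r], -_TIE_ORDER[r]))
    return label, posteriors


def fit_model(
    labeled_pairs: list[tuple[PairStats, str]],
    base: RelationshipModel | None = None,
    min_pairs: int = 30,
    mu_source: str = "empirical",
    freq: theory.FreqSpec = theory.FreqSpec(),
    S: int = 10_000,
) -> RelationshipModel:
    """Estimate model parameters from labelled pairs.

    FS/D2/D3 get sample means, SDs and Pearson correlation of
    (HGMR, AGMR); PO gets normal AGMR moments and an exponential rate
    k = 1/mean(HGMR) (method of moments; capped at ``K_RATE_CAP`` when
    every PO HGMR is zero).  Relationships with fewer than ``min_pairs``
    labelled pairs keep the ``base`` (default pooled) parameters.  With
    ``mu_source='analytic'`` the means are replaced by the closed-form
    expectations under ``freq`` while SDs and correlations stay empirical.
    """
    if mu_source not in ("empirical", "analytic"):
        raise ValueError("mu_source must be 'empirical' or 'analytic'")
    model = base if base is not None else default_model()
    by_rel: dict[str, list[tuple[float, float]]] = {r: [] for r in CLOSE_RELATIONSHIPS}
    for st, rel in labeled_pairs:
        if rel not in by_rel:
            continue
        if st.hgmr is None or st.agmr is None:
            continue
        by_rel[rel].append((st.hgmr, st.agmr))
    if not any(by_rel.values()):
        log.warning("fit_model: no usable labelled pairs; returning defaults")
        return model

    updates = {}
    for rel, vals in by_rel.items():
        if len(vals) < (min_pairs if rel != "PO" else min_pairs):
            if vals:
                log.warning(
                    "fit_model: only %d %s pairs (< %d); keeping defaults",
                    len(vals), rel, min_pairs,
                )
            continue
        x = np.array([v[0] for v in vals])
        y = np.array([v[1] for v in vals])
        mu_x, mu_y = float(x.mean()), float(y.mean())
        if mu_source == "analytic":
            prof = theory.PROFILES[rel]
            mu_x = theory.expected_hgmr(prof, freq)
            mu_y = theory.expected_agmr(prof, freq)
        if rel == "PO":
            k = K_RATE_CAP if x.mean() == 0.0 else min(1.0 / x.mean(), K_RATE_CAP)
            updates["po"] = POParams(
                k_rate=k, mu_y=mu_y, sd_y=float(y.std(ddof=1))
            )
        else:
            rho = float(np.corrcoef(x, y)[0, 1]) if len(vals) > 2 else 0.0
            if not -1.0 < rho < 1.0 or math.isnan(rho):
                rho = 0.0
            updates[rel.lower()] = BivariateParams(
                mu_x=mu_x,
                sd_x=float(x.std(ddof=1)),
                mu_y=mu_y,
                sd_y=float(y.std(ddof=1)),
                rho=rho,
            )
    return replace(model, **updates)


_ADJACENT = (("PO", "FS"), ("FS", "D2"), ("D2", "D3"))


def decision_boundaries(
    model: RelationshipModel,
    x_range: tuple[float, float] = (0.0, 0.25),
    y_range: tuple[float, float] = (0.25, 0.60),
    n_grid: int = 201,
) -> dict[tuple[str, str], np.ndarray]:
    """Equal-posterior loci between adjacent relationship classes.

    Evaluates the log prior-weighted densities on a grid and linearly
    interpolates the zero crossings of their difference along grid rows
    and columns.  Returned arrays have shape (n_points, 2) with columns
    (HGMR, AGMR).  Used for report scatter plots.
    """
    xs = np.linspace(*x_range, n_grid)
    ys = np.linspace(*y_range, n_grid)
    out: dict[tuple[str, str], np.ndarray] = {}
    logd = {}
    for rel in CLOSE_RELATIONSHIPS:
        vals = np.empty((n_grid, n_grid))
        for i, x in enumerate(xs):
            for j, y in enumerate(ys):
                d = model.priors[rel] * density(rel, float(x), float(y), model)
                vals[i, j] = math.log(d) if d > 0 else -math.inf
        logd[rel] = vals
    for r1, r2 in _ADJACENT:
        with np.errstate(invalid="ignore"):
            f = logd[r1] - logd[r2]
        pts: list[tuple[float, float]] = []
        finite = np.isfinite(f)
        # crossings along x (rows of constant y) and along y
        for axis in (0, 1):
            fa = f if axis == 0 else f.T
            fin = finite if axis == 0 else finite.T
            sign_change = (fa[:-1, :] * fa[1:, :] < 0) & fin[:-1, :] & fin[1:, :]
            ii, jj = np.nonzero(sign_change)
            for i, j in zip(ii, jj):
                t = fa[i, j] / (fa[i, j] - fa[i + 1, j])
                if axis == 0:
                    pts.append((xs[i] + t * (xs[i + 1] - xs[i]), ys[j]))
                else:
                    pts.append((ys[i] + t * (ys[i + 1] - ys[i]), xs[j])[::-1])
        out[(r1, r2)] = np.array(sorted(set(pts))) if pts else np.empty((0, 2))
    return out


_MODEL_COLUMNS = [
    "relationship", "mu_hgmr", "sd_hgmr", "mu_agmr", "sd_agmr", "rho", "k_rate",
]


def write_model(model: RelationshipModel, path) -> None:
    """Persist a model as TSV (one row per relationship; fractions)."""
    rows = [
        ("PO", "", "", model.po.mu_y, model.po.sd_y, 0.0, model.po.k_rate),
    ]
    for rel in ("FS", "D2", "D3"):
        b = model.params(rel)
        rows.append((rel, b.mu_x, b.sd_x, b.mu_y, b.sd_y, b.rho, ""))
    pd.DataFrame(rows, columns=_MODEL_COLUMNS).to_csv(path, sep="\t", index=False)


def read_model(path) -> RelationshipModel:
    df = pd.read_csv(path, sep="\t").set_index("relationship")
    po = df.loc["PO"]
    kwargs = {"po": POParams(float(po.k_rate), float(po.mu_agmr), float(po.sd_agmr))}
    for rel in ("FS", "D2", "D3"):
        r = df.loc[rel]
        kwargs[rel.lower()] = BivariateParams(
            float(r.mu_hgmr), float(r.sd_hgmr), float(r.mu_agmr), float(r.sd_agmr),
            float(r.rho),
        )
    return RelationshipModel(**kwargs)
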