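"""The four biometric similarity families.

* DAG semantic similarity between diseases, two variants: DSS1 from decayed
  ancestor contributions, DSS2 from information-content style contributions.
* Gaussian interaction profile (GIP) kernels over rows/columns of the
  association matrix, with a data-driven bandwidth.
* Expression-profile similarity: Spearman rank correlation between circRNA
  expression vectors.
* Jaccard similarity of association sets.

Every matrix returned is square and symmetric.  Where the printed formulas
in the source method are ambiguous or dimensionally inconsistent, the
standard form is the default and the literal printed form sits behind a
mode flag; see docs/methods.md for the rationale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core_io import AssociationMatrix, DiseaseDAG, ExpressionTable


@dataclass
class SemanticParams:
    """Parameters of the DAG semantic similarity.

    mu_semantic is the per-edge contribution decay: an ancestor reached
    through one parent edge contributes mu, through two edges mu^2, and so
    on (along the best path).  Default 0.5.
    """

    mu_semantic: float = 0.5
    dss2_mode: str = "information_content"  # or "literal"

    def __post_init__(self) -> None:
        if not (0 < self.mu_semantic <= 1):
            raise ValueError("mu_semantic must be in (0, 1]")
        if self.dss2_mode not in ("information_content", "literal"):
            raise ValueError("dss2_mode must be 'information_content' or 'literal'")


@dataclass
class SimilarityBundle:
    """The named similarity matrices the fusion stage consumes.

    Disease side (n x n): DSS1, DSS2, GD, JD.  circRNA side (m x m): GC, SE,
    JC.  ``semantic_mask``/``expression_mask`` flag which diseases appear in
    the ontology and which circRNAs have expression profiles; fusion falls
    back to the GIP kernel where a mask is False.
    """

    DSS1: np.ndarray
    DSS2: np.ndarray
    GD: np.ndarray
    JD: np.ndarray
    GC: np.ndarray
    SE: np.ndarray
    JC: np.ndarray
    semantic_mask: np.ndarray
    expression_mask: np.ndarray


# ---------------------------------------------------------------------------
# DAG semantic similarity
# ---------------------------------------------------------------------------

def disease_contribution(dag: DiseaseDAG, d: str, params: SemanticParams | None = None) -> dict[str, float]:
    """Decayed contribution D_d(e) of every ancestor e to disease d.

    D_d(d) = 1; for any other ancestor e, D_d(e) = max over children e' of e
    inside d's DAG of mu * D_d(e').  Computed in one pass outward from d.
    """
    params = params or SemanticParams()
    if d not in dag:
        raise KeyError(f"disease {d!r} not in DAG")
    nd = dag.ancestors(d)
    contrib: dict[str, float] = {d: 1.0}
    # process nodes in order of increasing distance from d: repeatedly relax
    # parent values from already-known children (DAG is small; fixpoint loop).
    remaining = set(nd) - {d}
    while remaining:
        progressed = False
        for e in list(remaining):
            children = dag.children_within(e, d)
            vals = [contrib[c] for c in children if c in contrib]
            if vals and len(vals) == len(children):
                contrib[e] = params.mu_semantic * max(vals)
                remaining.discard(e)
                progressed = True
        if not progressed:  # pragma: no cover - acyclicity guarantees progress
            raise RuntimeError("failed to resolve contributions; DAG inconsistent")
    return contrib


def semantic_value(dag: DiseaseDAG, d: str, params: SemanticParams | None = None) -> float:
    """DV(d): sum of decayed contributions over d's ancestor closure (>= 1)."""
    return float(sum(disease_contribution(dag, d, params).values()))


def _dag_diseases(dag: DiseaseDAG, disease_ids: list[str]) -> np.ndarray:
    return np.array([d in dag for d in disease_ids], dtype=bool)


def dss1(dag: DiseaseDAG, disease_ids: list[str], params: SemanticParams | None = None) -> np.ndarray:
    """Semantic similarity from shared weighted ancestors.

    DSS1(i, j) = sum over shared ancestors e of (D_i(e) + D_j(e)) divided by
    DV(i) + DV(j).  Diseases absent from the DAG get zero rows/columns (the
    fusion stage substitutes the GIP kernel there); the diagonal is 1 for
    present diseases.
    """
    params = params or SemanticParams()
    n = len(disease_ids)
    present = _dag_diseases(dag, disease_ids)
    contribs = {d: disease_contribution(dag, d, params) for d, ok in zip(disease_ids, present) if ok}
    dv = {d: sum(c.values()) for d, c in contribs.items()}
    out = np.zeros((n, n))
    for i, di in enumerate(disease_ids):
        if not present[i]:
            continue
        for j in range(i, n):
            dj = disease_ids[j]
            if not present[j]:
                continue
            shared = set(contribs[di]) & set(contribs[dj])
            num = sum(contribs[di][e] + contribs[dj][e] for e in shared)
            out[i, j] = out[j, i] = num / (dv[di] + dv[dj])
    return out


def dss2(dag: DiseaseDAG, disease_ids: list[str], params: SemanticParams | None = None) -> np.ndarray:
    """Semantic similarity with rarity-weighted ancestor contributions.

    In information_content mode the contribution of ancestor e is
    -log(num(e) / num(diseases)) with num(e) the number of disease DAGs that
    contain e: ancestors shared by everything contribute nothing, rare
    shared ancestors contribute a lot.  The literal mode instead uses
    |N_d| / num(diseases), constant over e, reproducing the printed formula.
    The raw matrix is clipped at zero and rescaled to [0, 1] by its maximum
    (the contributions themselves are unbounded).
    """
    params = params or SemanticParams()
    n = len(disease_ids)
    present = _dag_diseases(dag, disease_ids)
    if present.sum() == 0:
        return np.zeros((n, n))
    contribs = {d: disease_contribution(dag, d, params) for d, ok in zip(disease_ids, present) if ok}
    dv = {d: sum(c.values()) for d, c in contribs.items()}
    n_total = len(dag.nodes)
    # count, for each node, how many disease closures contain it
    count: dict[str, int] = {}
    for d in dag.nodes:
        for e in dag.ancestors(d):
            count[e] = count.get(e, 0) + 1
    out = np.zeros((n, n))
    for i, di in enumerate(disease_ids):
        if not present[i]:
            continue
        ni = dag.ancestors(di)
        for j in range(i, n):
            dj = disease_ids[j]
            if not present[j]:
                continue
            shared = ni & dag.ancestors(dj)
            if params.dss2_mode == "information_content":
                num = sum(2.0 * -np.log(count[e] / n_total) for e in shared)
            else:
                ci = -np.log(len(ni) / n_total)
                cj = -np.log(len(dag.ancestors(dj)) / n_total)
                num = sum(ci + cj for _ in shared)
            out[i, j] = out[j, i] = num / (dv[di] + dv[dj])
    out = np.clip(out, 0.0, None)
    mx = out.max()
    if mx > 0:
        out /= mx
    return out


# ---------------------------------------------------------------------------
# Gaussian interaction profile kernel
# ---------------------------------------------------------------------------

def gip_bandwidth(profiles: np.ndarray) -> float:
    """Mean squared norm of the interaction profiles (rows of ``profiles``)."""
    profiles = np.asarray(profiles, dtype=float)
    mu_bar = float(np.mean(np.sum(profiles**2, axis=1)))
    if mu_bar == 0.0:
        raise ValueError("GIP undefined on empty association matrix")
    return mu_bar


def gip_kernel(am: AssociationMatrix | np.ndarray, axis: str, literal: bool = False) -> np.ndarray:
    """GIP kernel over association profiles.

    axis='disease' uses the columns of AM as profiles (n x n output),
    axis='circRNA' the rows (m x m).  The kernel is
    exp(-gamma * ||V_i - V_j||^2) with gamma = 1 / mean squared profile norm
    by default; ``literal=True`` multiplies by the mean squared norm instead.
    """
    mat = am.AM if isinstance(am, AssociationMatrix) else np.asarray(am)
    if axis == "disease":
        profiles = mat.T.astype(float)
    elif axis == "circRNA":
        profiles = mat.astype(float)
    else:
        raise ValueError("axis must be 'disease' or 'circRNA'")
    mu_bar = gip_bandwidth(profiles)
    gamma = mu_bar if literal else 1.0 / mu_bar
    sq = np.sum(profiles**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * profiles @ profiles.T
    d2 = np.maximum(d2, 0.0)
    k = np.exp(-gamma * d2)
    np.fill_diagonal(k, 1.0)
    return k


# ---------------------------------------------------------------------------
# expression-profile similarity
# ---------------------------------------------------------------------------

def expression_similarity(expr: ExpressionTable, mode: str = "standard") -> np.ndarray:
    """Pairwise Spearman rank correlation of expression profiles.

    standard: tie-aware Spearman (rank then Pearson) over the p-dimensional
    profiles; entries in [-1, 1], diagonal 1.  literal: the printed
    rho = 1 - 6 sum(d_p^2) / (k (k - 1)) with d_p the difference of the
    descending-sorted profiles and k the number of circRNAs — unbounded and
    kept only for faithfulness comparisons.

    Constant profiles have no rank variance; their similarity is defined as
    0 (with a warning), diagonal excepted.
    """
    x = expr.profiles
    k, p = x.shape
    if p < 2:
        raise ValueError("need at least 2 expression dimensions")
    if mode == "standard":
        if k == 1:
            return np.ones((1, 1))
        const = x.std(axis=1) == 0
        if const.any():
            warnings.warn(f"{int(const.sum())} constant profile(s); similarity set to 0", stacklevel=2)
        ranks = np.apply_along_axis(stats.rankdata, 1, x)
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = np.corrcoef(ranks)
        rho = np.asarray(rho, dtype=float)
        rho[~np.isfinite(rho)] = 0.0
        np.fill_diagonal(rho, 1.0)
        rho[const, :] = 0.0
        rho[:, const] = 0.0
        np.fill_diagonal(rho, 1.0)
        return (rho + rho.T) / 2.0
    if mode == "literal":
        srt = -np.sort(-x, axis=1)  # descending sort of each profile
        out = np.empty((k, k))
        denom = k * (k - 1) if k > 1 else 1
        for i in range(k):
            d = srt[i] - srt[i + 1 :]
            out[i, i] = 1.0
            if len(d):
                vals = 1.0 - 6.0 * np.sum(d**2, axis=1) / denom
                out[i, i + 1 :] = vals
                out[i + 1 :, i] = vals
        return out
    raise ValueError("mode must be 'standard' or 'literal'")


# ---------------------------------------------------------------------------
# Jaccard similarity
# ---------------------------------------------------------------------------

def jaccard(am: AssociationMatrix | np.ndarray, axis: str) -> np.ndarray:
    """Intersection-over-union of association sets.

    axis='disease': sets are the circRNAs associated with each disease
    (columns of AM); axis='circRNA': the diseases per circRNA (rows).
    Pairs where both sets are empty get similarity 0.
    """
    mat = am.AM if isinstance(am, AssociationMatrix) else np.asarray(am)
    prof = (mat.T if axis == "disease" else mat).astype(float)
    if axis not in ("disease", "circRNA"):
        raise ValueError("axis must be 'disease' or 'circRNA'")
    inter = prof @ prof.T
    sizes = prof.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(union > 0, inter / np.maximum(union, 1e-300), 0.0)
    return out


# ---------------------------------------------------------------------------
# bundle construction
# ---------------------------------------------------------------------------

def build_bundle(
    am: AssociationMatrix,
    dag: DiseaseDAG | None,
    expr: ExpressionTable | None,
    params: SemanticParams | None = None,
    se_mode: str = "standard",
    gip_literal: bool = False,
) -> SimilarityBundle:
    """Compute all seven similarity matrices for one association matrix.

    ``dag`` / ``expr`` may be None (no ontology / no expression data), in
    which case the corresponding masks are all-False and fusion will use the
    GIP kernels alone.  Expression rows are matched to ``am.circ_ids`` by
    identifier; unprofiled circRNAs get zero SE rows and a False mask entry.
    """
    params = params or SemanticParams()
    n, m = am.n, am.m
    if dag is not None:
        d1 = dss1(dag, am.disease_ids, params)
        d2 = dss2(dag, am.disease_ids, params)
        smask = _dag_diseases(dag, am.disease_ids)
    else:
        d1 = np.zeros((n, n))
        d2 = np.zeros((n, n))
        smask = np.zeros(n, dtype=bool)
    gd = gip_kernel(am, "disease", literal=gip_literal)
    gc = gip_kernel(am, "circRNA", literal=gip_literal)
    jd = jaccard(am, "disease")
    jc = jaccard(am, "circRNA")
    se = np.zeros((m, m))
    emask = np.zeros(m, dtype=bool)
    if expr is not None:
        idx = {c: i for i, c in enumerate(expr.circ_ids)}
        have = [i for i, c in enumerate(am.circ_ids) if c in idx]
        emask[have] = True
        if have:
            sub = ExpressionTable(
                [am.circ_ids[i] for i in have],
                expr.profiles[[idx[am.circ_ids[i]] for i in have]],
            )
            se_sub = expression_similarity(sub, mode=se_mode)
            se[np.ix_(have, have)] = se_sub
    return SimilarityBundle(d1, d2, gd, jd, gc, se, jc, smask, emask)
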