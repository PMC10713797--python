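"""Regularized joint-probability-distribution adaptation with dual selection.

Given selected tangent-space features from a labeled source subject pool and
an unlabeled target subject, this module learns a pair of linear maps
ω = [ω_s; ω_t] that embeds both domains into a common space where

* same-class cross-domain means coincide (transferability MMD term),
* different-class cross-domain means are pushed apart (discriminability MMD
  term, weighted by λ),
* source classes stay compact (within-class scatter, weight η) and separated
  (between-class scatter in the constraint),
* target locality is preserved on a heat-kernel graph (normalized Laplacian,
  weight μ), with a centering constraint limiting scale collapse,
* ω_s and ω_t stay close and bounded (weight σ).

The Lagrangian stationarity condition is a symmetric-definite generalized
eigenproblem G ω = ρ E ω whose trailing (smallest-eigenvalue) eigenvectors
give the embedding.  The target's conditional terms require pseudo-labels,
which come from a nearest-class-prototype soft classifier in the embedded
space; over T outer iterations a class-balanced, confidence-ranked subset of
pseudo-labeled target samples grows from roughly n_t/T to all of n_t,
shielding the conditional alignment from early mislabels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .exceptions import InvalidInputError
from .mefs import GraphLaplacian, build_graph_laplacian
from .spd import FeatureSet

__all__ = [
    "AdaptConfig",
    "LabelMatrices",
    "AdaptOperators",
    "AdaptResult",
    "build_scatter_matrices",
    "build_label_matrices",
    "assemble_operators",
    "solve_transform",
    "class_prototypes",
    "pseudo_label_probabilities",
    "select_pseudo_labels",
    "fit_dsktl_binary",
]


@dataclass
class AdaptConfig:
    """Tunable parameters of the adaptation stage.

    Defaults follow the method's recommended settings: η = 0.01, μ = 0.1,
    σ = 20 for the three regularizers; λ = 0.1 trade-off between
    transferability and discriminability; z = 10 embedded dimensions; T = 5
    pseudo-label selection iterations.  ``ridge=None`` applies an automatic
    relative ridge ``1e-8 · tr(E)/(2q)`` to keep E positive definite.
    """

    lam: float = 0.1
    z: int = 10
    T: int = 5
    eta: float = 0.01
    mu: float = 0.1
    sigma: float = 20.0
    ridge: float | None = None
    disable_pseudo_selection: bool = False
    shrink_all_terms: bool = False
    graph_bandwidth: float | str = "auto"
    graph_k: int | None = None


@dataclass
class LabelMatrices:
    """Class-indicator matrices entering the two MMD terms.

    ``P`` columns are per-class indicators normalized by the class count, so
    ``ωᵀ f P`` gives class means; ``Q`` columns enumerate the C(C−1) ordered
    class pairs (c, c′): the source column indicates class c, the target
    column class c′, so the Q-term measures cross-class mean discrepancies.
    Target matrices are built from pseudo-labels restricted to the currently
    selected sample subset; a class with no selected sample contributes a
    zero column and its term drops.
    """

    P_s: np.ndarray
    P_t: np.ndarray
    Q_s: np.ndarray
    Q_t: np.ndarray
    classes: np.ndarray


@dataclass
class AdaptOperators:
    """Assembled matrices of the generalized eigenproblem G ω = ρ E ω."""

    G: np.ndarray
    E: np.ndarray
    A_min: np.ndarray
    A_max: np.ndarray
    S_w: np.ndarray
    S_b: np.ndarray
    H: np.ndarray
    lam: float
    eta: float
    mu: float
    sigma: float


@dataclass
class AdaptResult:
    """Output of the adaptation loop."""

    omega: np.ndarray
    u_s: np.ndarray
    u_t: np.ndarray
    prototypes: np.ndarray
    pseudo_labels: np.ndarray
    probabilities: np.ndarray
    selected_per_iter: np.ndarray
    eigenvalues: np.ndarray
    classes: np.ndarray = field(default_factory=lambda: np.array([]))


# ---------------------------------------------------------------------------
# scatter and label matrices


def build_scatter_matrices(f_s: FeatureSet) -> tuple[np.ndarray, np.ndarray]:
    """Within-class and between-class scatter of labeled source features.

    ``S_w = Σ_c Σ_{i∈c} (f_i − m_c)(f_i − m_c)ᵀ`` and
    ``S_b = Σ_c n_c (m_c − m)(m_c − m)ᵀ`` with class means m_c and global
    mean m; both are symmetric PSD q × q matrices.
    """
    if f_s.labels is None:
        raise InvalidInputError("scatter matrices need labeled features")
    x = f_s.features
    labels = f_s.labels
    classes = np.unique(labels)
    if classes.size < 2:
        raise InvalidInputError("need at least two classes")
    q = x.shape[1]
    m = x.mean(axis=0)
    s_w = np.zeros((q, q))
    s_b = np.zeros((q, q))
    for c in classes:
        xc = x[labels == c]
        if xc.shape[0] == 0:
            raise InvalidInputError(f"class {c} is empty")
        mc = xc.mean(axis=0)
        d = xc - mc
        s_w += d.T @ d
        dm = (mc - m)[:, None]
        s_b += xc.shape[0] * (dm @ dm.T)
    return 0.5 * (s_w + s_w.T), 0.5 * (s_b + s_b.T)


def build_label_matrices(
    y_s: np.ndarray,
    y_t: np.ndarray,
    selected: np.ndarray | None = None,
    classes: np.ndarray | None = None,
) -> LabelMatrices:
    """Normalized class-indicator matrices for the two MMD terms.

    Parameters
    ----------
    y_s:
        Complete source labels, length n_s.
    y_t:
        Target pseudo-labels, length n_t.
    selected:
        Indices of the currently selected pseudo-labeled target samples;
        ``None`` selects all.  Unselected rows of P_t / Q_t are zero.
    classes:
        Explicit class values; defaults to the unique source labels.
    """
    y_s = np.asarray(y_s)
    y_t = np.asarray(y_t)
    if classes is None:
        classes = np.unique(y_s)
    if not np.all(np.isin(y_s, classes)):
        raise InvalidInputError("source labels outside the declared class set")
    sel_mask = np.zeros(y_t.size, dtype=bool)
    if selected is None:
        sel_mask[:] = True
    else:
        sel_mask[np.asarray(selected, dtype=int)] = True
    if sel_mask.any() and not np.all(np.isin(y_t[sel_mask], classes)):
        raise InvalidInputError("target pseudo-labels outside the declared class set")

    c_n = classes.size

    def _indicator(y: np.ndarray, mask: np.ndarray) -> np.ndarray:
        out = np.zeros((y.size, c_n))
        for j, c in enumerate(classes):
            col = (y == c) & mask
            cnt = int(col.sum())
            if cnt > 0:
                out[col, j] = 1.0 / cnt
        return out

    p_s = _indicator(y_s, np.ones(y_s.size, dtype=bool))
    p_t = _indicator(y_t, sel_mask)

    pairs = [(a, b) for a in range(c_n) for b in range(c_n) if a != b]
    q_s = np.zeros((y_s.size, len(pairs)))
    q_t = np.zeros((y_t.size, len(pairs)))
    for k, (a, b) in enumerate(pairs):
        q_s[:, k] = p_s[:, a]
        q_t[:, k] = p_t[:, b]
    return LabelMatrices(P_s=p_s, P_t=p_t, Q_s=q_s, Q_t=q_t, classes=classes)


# ---------------------------------------------------------------------------
# operator assembly and eigen solve


def _blockdiag(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return scipy.linalg.block_diag(a, b)


def centering_matrix(n: int) -> np.ndarray:
    """H = I − (1/n)·11ᵀ, the idempotent column-centering projector."""
    return np.eye(n) - np.full((n, n), 1.0 / n)


def assemble_operators(
    f_s: FeatureSet,
    f_t: FeatureSet,
    label_mats: LabelMatrices,
    s_w: np.ndarray,
    s_b: np.ndarray,
    target_graph: GraphLaplacian,
    lam: float,
    eta: float,
    mu: float,
    sigma: float,
) -> AdaptOperators:
    """Assemble G and E of the generalized eigenproblem term by term.

    With column-oriented data F = blockdiag(F_s, F_t) (F_s q × n_s,
    F_t q × n_t) and stacked ω = [ω_s; ω_t]:

        G = F (A_min − λ A_max) Fᵀ + η·blockdiag(S_w, 0)
            + μ·blockdiag(0, F_t L_t F_tᵀ) + σ·[[I, −I], [−I, 2I]]
        E = blockdiag(S_b, F_t H F_tᵀ)

    where A_min / A_max are the block MMD coefficient matrices built from the
    P / Q label matrices, L_t is the normalized target graph Laplacian and H
    the target centering projector.  Both outputs are symmetrized.
    """
    fs = f_s.features.T  # q × n_s
    ft = f_t.features.T  # q × n_t
    q = fs.shape[0]
    if ft.shape[0] != q:
        raise InvalidInputError("source/target feature dimensions differ")
    n_s, n_t = fs.shape[1], ft.shape[1]
    lm = label_mats
    if lm.P_s.shape[0] != n_s or lm.P_t.shape[0] != n_t:
        raise InvalidInputError("label matrices do not match feature counts")

    def _mmd_block(ms: np.ndarray, mt: np.ndarray) -> np.ndarray:
        top = np.hstack([ms @ ms.T, -ms @ mt.T])
        bot = np.hstack([-mt @ ms.T, mt @ mt.T])
        return np.vstack([top, bot])

    a_min = _mmd_block(lm.P_s, lm.P_t)
    a_max = _mmd_block(lm.Q_s, lm.Q_t)

    f_block = _blockdiag(fs, ft)  # 2q × (n_s + n_t)
    g = f_block @ (a_min - lam * a_max) @ f_block.T
    g += eta * _blockdiag(s_w, np.zeros((q, q)))
    l_t = target_graph.normalized_laplacian
    if l_t.shape[0] != n_t:
        raise InvalidInputError("target graph size does not match n_t")
    g += mu * _blockdiag(np.zeros((q, q)), ft @ l_t @ ft.T)
    eye = np.eye(q)
    coupling = np.block([[eye, -eye], [-eye, 2.0 * eye]])
    g += sigma * coupling

    h = centering_matrix(n_t)
    e = _blockdiag(s_b, ft @ h @ ft.T)
    return AdaptOperators(
        G=0.5 * (g + g.T),
        E=0.5 * (e + e.T),
        A_min=a_min,
        A_max=a_max,
        S_w=s_w,
        S_b=s_b,
        H=h,
        lam=lam,
        eta=eta,
        mu=mu,
        sigma=sigma,
    )


def solve_transform(
    ops: AdaptOperators,
    z: int,
    ridge: float | None = None,
    range_tol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray]:
    """Solve G ω = ρ (E + ridge·I) ω for the z smallest-eigenvalue vectors.

    E is PSD and typically rank deficient (the between-class scatter block
    has rank C − 1), so the pencil is solved on E's numerical range: E's
    eigendirections below ``range_tol`` times its largest eigenvalue are
    projected out, which bounds eigenvector norms and keeps near-null
    directions — meaningless under the normalization constraint — out of the
    embedding.  The objective is a minimization, so the trailing
    (algebraically smallest) eigenvalues are kept; the returned columns are
    (E + ridge·I)-orthonormal on the retained subspace and the eigenvalues
    sorted ascending.  If the retained rank r is below z, the embedding has
    r columns.
    """
    g, e = ops.G, ops.E
    dim = g.shape[0]
    if not 1 <= z <= dim:
        raise InvalidInputError(f"z must be in [1, {dim}], got {z}")
    if ridge is None:
        ridge = 1e-8 * float(np.trace(e)) / dim
    w_e, v_e = scipy.linalg.eigh(e)
    keep = w_e > range_tol * max(w_e[-1], 0.0)
    if not keep.any():
        raise InvalidInputError("E is numerically zero; nothing to normalize")
    basis = v_e[:, keep]
    g_r = basis.T @ g @ basis
    e_r = basis.T @ e @ basis + ridge * np.eye(int(keep.sum()))
    w, v = scipy.linalg.eigh(0.5 * (g_r + g_r.T), e_r)
    z_eff = min(z, v.shape[1])
    return basis @ v[:, :z_eff], w[:z_eff]


# ---------------------------------------------------------------------------
# prototype classifier and pseudo-label selection


def class_prototypes(
    u_s: np.ndarray, y_s: np.ndarray, classes: np.ndarray | None = None
) -> np.ndarray:
    """Per-class means of the embedded source samples, shape (C, z)."""
    u_s = np.asarray(u_s, dtype=float)
    y_s = np.asarray(y_s)
    if classes is None:
        classes = np.unique(y_s)
    protos = np.empty((classes.size, u_s.shape[1]))
    for j, c in enumerate(classes):
        mask = y_s == c
        if not mask.any():
            raise InvalidInputError(f"class {c} has no source samples")
        protos[j] = u_s[mask].mean(axis=0)
    return protos


def pseudo_label_probabilities(
    u_t: np.ndarray, prototypes: np.ndarray, classes: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Soft nearest-prototype classification of embedded target samples.

    Class posteriors are a softmax over negative Euclidean distances to the
    source prototypes; labels are the row argmax with ties resolved in favour
    of the lower class index.
    """
    u_t = np.asarray(u_t, dtype=float)
    prototypes = np.asarray(prototypes, dtype=float)
    if prototypes.shape[0] < 2:
        raise InvalidInputError("need at least two class prototypes")
    d = np.linalg.norm(u_t[:, None, :] - prototypes[None, :, :], axis=2)
    logits = -d
    logits -= logits.max(axis=1, keepdims=True)
    expd = np.exp(logits)
    probs = expd / expd.sum(axis=1, keepdims=True)
    label_idx = np.argmax(probs, axis=1)  # argmax returns the first maximum
    if classes is None:
        classes = np.arange(1, prototypes.shape[0] + 1)
    return probs, np.asarray(classes)[label_idx]


def select_pseudo_labels(
    probabilities: np.ndarray,
    pseudo_labels: np.ndarray,
    iteration: int,
    T: int,
    n_t_per_class: dict | np.ndarray,
    classes: np.ndarray | None = None,
) -> np.ndarray:
    """Class-wise confidence-ranked selection for iteration ``i`` of ``T``.

    For each class c the quota is ``ceil(i · n_t^c / T)`` samples, filled by
    the highest-posterior samples currently assigned to c; if a class's pool
    is smaller than its quota, the shortfall is topped up from the globally
    most confident unselected samples so the total matches the schedule.
    Ties are broken deterministically: higher probability first, then lower
    sample index.  Returns sorted sample indices.
    """
    if not 1 <= iteration <= T:
        raise InvalidInputError("iteration must be in [1, T]")
    probabilities = np.asarray(probabilities, dtype=float)
    pseudo_labels = np.asarray(pseudo_labels)
    n_t = pseudo_labels.size
    if classes is None:
        classes = np.unique(pseudo_labels)
    if isinstance(n_t_per_class, dict):
        counts = np.array([n_t_per_class[c] for c in classes])
    else:
        counts = np.asarray(n_t_per_class)
    conf = probabilities.max(axis=1)
    order_key = np.lexsort((np.arange(n_t), -conf))  # conf desc, index asc
    rank = np.empty(n_t, dtype=int)
    rank[order_key] = np.arange(n_t)

    selected = np.zeros(n_t, dtype=bool)
    shortfall = 0
    for j, c in enumerate(classes):
        quota = min(math.ceil(iteration * counts[j] / T), n_t)
        pool = np.flatnonzero(pseudo_labels == c)
        pool = pool[np.argsort(rank[pool])]
        take = pool[:quota]
        selected[take] = True
        shortfall += max(0, quota - take.size)
    if shortfall > 0:
        rest = np.flatnonzero(~selected)
        rest = rest[np.argsort(rank[rest])]
        selected[rest[:shortfall]] = True
    return np.flatnonzero(selected)


# ---------------------------------------------------------------------------
# full binary adaptation loop


def _embed(omega: np.ndarray, fs: np.ndarray, ft: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    q = fs.shape[0]
    w_s, w_t = omega[:q], omega[q:]
    return (w_s.T @ fs).T, (w_t.T @ ft).T


def fit_dsktl_binary(
    f_s: FeatureSet,
    f_t: FeatureSet,
    config: AdaptConfig | None = None,
) -> AdaptResult:
    """Run the full two-class adaptation with incremental pseudo-labeling.

    Initial pseudo-labels come from the nearest-class-prototype rule applied
    directly in the selected feature space (identity transform) — the same
    classifier used inside the loop, before any adaptation; the iteration-1
    class-balanced subset is selected from the resulting posteriors.  Each
    of the T subsequent iterations
    rebuilds the conditional MMD terms from the selected subset only (the
    Laplacian and centering terms always use all target samples, unless
    ``shrink_all_terms``), re-solves the eigenproblem, re-labels, and grows
    the selection; after iteration T every target sample is selected and
    carries a label and posterior.

    Per-class schedule counts are frozen from the initial labeling so the
    selection sizes Σ_c ceil(i·n_t^c/T) are deterministic and nondecreasing.
    """
    cfg = config or AdaptConfig()
    if f_s.labels is None:
        raise InvalidInputError("source features must be labeled")
    classes = np.unique(f_s.labels)
    if classes.size != 2:
        raise InvalidInputError(
            "the adaptation classifier is binary; decompose multi-class "
            "problems into class pairs (see dsktl.pipeline.enumerate_tasks)"
        )
    if f_s.dim != f_t.dim:
        raise InvalidInputError("source/target feature dimensions differ")
    q = f_s.dim
    if cfg.z > 2 * q:
        raise InvalidInputError(f"z={cfg.z} exceeds 2q={2 * q}")
    fs = f_s.features.T
    ft = f_t.features.T
    y_s = f_s.labels
    n_t = ft.shape[1]

    s_w, s_b = build_scatter_matrices(f_s)
    graph_t = build_graph_laplacian(
        f_t, bandwidth=cfg.graph_bandwidth, k_neighbors=cfg.graph_k
    )

    def _solve(selected: np.ndarray, y_t: np.ndarray):
        lm = build_label_matrices(y_s, y_t, selected=selected, classes=classes)
        if cfg.shrink_all_terms:
            sub = np.asarray(selected, dtype=int)
            ft_sub = FeatureSet(ft.T[sub], domain_tag="target")
            graph_sub = build_graph_laplacian(
                ft_sub, bandwidth=cfg.graph_bandwidth, k_neighbors=cfg.graph_k
            )
            lm_sub = build_label_matrices(y_s, y_t[sub], classes=classes)
            ops = assemble_operators(
                f_s, ft_sub, lm_sub, s_w, s_b, graph_sub,
                cfg.lam, cfg.eta, cfg.mu, cfg.sigma,
            )
            return solve_transform(ops, cfg.z, cfg.ridge)
        ops = assemble_operators(
            f_s, f_t, lm, s_w, s_b, graph_t, cfg.lam, cfg.eta, cfg.mu, cfg.sigma
        )
        return solve_transform(ops, cfg.z, cfg.ridge)

    # initial pseudo-labels: prototype rule in the raw selected feature space
    protos = class_prototypes(f_s.features, y_s, classes)
    probs, y_t = pseudo_label_probabilities(f_t.features, protos, classes)

    # schedule counts frozen from the initial labeling
    counts = np.array([int(np.sum(y_t == c)) for c in classes])
    if counts.min() == 0:  # degenerate initial labeling: split evenly
        counts = np.full(classes.size, n_t // classes.size)
        counts[: n_t - counts.sum()] += 1

    selected = select_pseudo_labels(probs, y_t, 1, cfg.T, counts, classes)
    if cfg.disable_pseudo_selection:
        selected = np.arange(n_t)

    selected_per_iter = []
    for i in range(1, cfg.T + 1):
        omega, eigvals = _solve(selected, y_t)
        u_s, u_t = _embed(omega, fs, ft)
        protos = class_prototypes(u_s, y_s, classes)
        probs, y_t = pseudo_label_probabilities(u_t, protos, classes)
        if cfg.disable_pseudo_selection:
            selected = np.arange(n_t)
        else:
            selected = select_pseudo_labels(probs, y_t, i, cfg.T, counts, classes)
        selected_per_iter.append(selected.size)

    return AdaptResult(
        omega=omega,
        u_s=u_s,
        u_t=u_t,
        prototypes=protos,
        pseudo_labels=y_t,
        probabilities=probs,
        selected_per_iter=np.asarray(selected_per_iter),
        eigenvalues=eigvals,
        classes=classes,
    )
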