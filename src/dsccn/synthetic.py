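"""Synthetic multi-omics generators with planted, bookkept ground truth.

Three generators cover the statistical structure the pipeline assumes:

* a two-group differential-expression cohort with planted high/low features on
  a positive raw expression scale (log-normal), so fold change as a ratio of
  group means is well defined;
* a paired pair of omics matrices sharing one sparse canonical pair, with
  block-contiguous support on the mRNA-like side (matching the fused penalty's
  adjacency assumption) and graph-clustered support on the methylation-like
  side (cliques of a planted block graph, matching the graph-guided penalty);
* a multi-class subtyped dataset layering class-mean shifts on the canonical
  supports, plus a healthy cohort in which the support features are expressed
  at a lower baseline so the differential-expression stage retains them.

Every generator is a pure function of its spec (one RNG stream seeded from the
spec) and returns exhaustive planted-truth bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import OmicsDataset

__all__ = [
    "InvalidSpecError",
    "DECohortSpec",
    "CanonicalPairSpec",
    "SubtypeSpec",
    "generate_de_cohort",
    "generate_canonical_pair",
    "generate_subtyped_dataset",
]

#: Fixed label alphabet for subtypes; classes beyond the fourth get "C5", "C6", ...
SUBTYPE_ALPHABET = ("Basal", "Her2", "LumA", "LumB")


class InvalidSpecError(ValueError):
    """A generator spec violates its invariants."""


@dataclass(frozen=True)
class DECohortSpec:
    """Two-group cohort with planted differentially expressed features.

    Expression values live on a positive raw scale: ``2 ** (baseline + shift +
    noise)`` with per-feature baselines on the log2 scale, so a planted shift
    of ``effect_log2fc`` corresponds to a fold change of about
    ``2 ** effect_log2fc``.
    """

    n_healthy: int
    n_disease: int
    n_features: int
    frac_high: float = 0.1
    frac_low: float = 0.05
    effect_log2fc: float = 2.0
    noise_sd: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_healthy, self.n_disease, self.n_features) <= 0:
            raise InvalidSpecError("cohort dimensions must be positive")
        if not (0 <= self.frac_high <= 1 and 0 <= self.frac_low <= 1):
            raise InvalidSpecError("planted fractions must lie in [0, 1]")
        if self.frac_high + self.frac_low > 1:
            raise InvalidSpecError("frac_high + frac_low must not exceed 1")
        if self.effect_log2fc < 0 or self.noise_sd < 0:
            raise InvalidSpecError("effect_log2fc and noise_sd must be non-negative")


@dataclass(frozen=True)
class CanonicalPairSpec:
    """Paired matrices sharing one sparse canonical pair.

    A latent factor z drives the columns in ``support_u`` of X; a correlated
    latent (Pearson correlation ``latent_corr`` with z) drives the columns in
    ``support_v`` of Y.  Off-support columns are independent unit-variance
    noise around their baselines.  The methylation-side feature space carries a
    planted block graph: consecutive blocks of ``graph_block_size`` features
    form cliques, and ``support_v`` is expected (not enforced) to be a union of
    such cliques.
    """

    s: int
    m: int
    n: int
    support_u: tuple[int, ...]
    support_v: tuple[int, ...]
    latent_corr: float = 0.9
    noise_sd: float = 0.5
    seed: int = 0
    graph_block_size: int = 5

    @classmethod
    def with_block_supports(
        cls,
        s: int,
        m: int,
        n: int,
        k_u: int = 10,
        k_v: int = 10,
        u_start: int = 0,
        v_start: int = 0,
        **kwargs,
    ) -> "CanonicalPairSpec":
        """Contiguous u-support of size ``k_u`` and clique-aligned v-support."""
        return cls(
            s=s,
            m=m,
            n=n,
            support_u=tuple(range(u_start, u_start + k_u)),
            support_v=tuple(range(v_start, v_start + k_v)),
            **kwargs,
        )

    def validate(self) -> None:
        if min(self.s, self.m, self.n) <= 0:
            raise InvalidSpecError("matrix dimensions must be positive")
        if len(self.support_u) == 0 or len(self.support_v) == 0:
            raise InvalidSpecError("empty canonical supports are not allowed")
        if len(set(self.support_u)) > self.m or len(set(self.support_v)) > self.n:
            raise InvalidSpecError("support larger than the feature space")
        if any(k < 0 or k >= self.m for k in self.support_u):
            raise InvalidSpecError("support_u index out of range")
        if any(k < 0 or k >= self.n for k in self.support_v):
            raise InvalidSpecError("support_v index out of range")
        if not (0 < self.latent_corr < 1):
            raise InvalidSpecError("latent_corr must lie strictly in (0, 1)")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be non-negative")
        if self.graph_block_size <= 0:
            raise InvalidSpecError("graph_block_size must be positive")


@dataclass(frozen=True)
class SubtypeSpec:
    """Multi-class structure layered on the canonical supports."""

    class_sizes: tuple[int, ...]
    class_shift: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if len(self.class_sizes) < 2:
            raise InvalidSpecError("need at least two classes")
        if any(int(c) <= 0 for c in self.class_sizes):
            raise InvalidSpecError("class sizes must be positive")
        if self.class_shift < 0:
            raise InvalidSpecError("class_shift must be non-negative")

    @property
    def labels(self) -> list[str]:
        names = list(SUBTYPE_ALPHABET)
        for i in range(len(names), len(self.class_sizes)):
            names.append(f"C{i + 1}")
        return names[: len(self.class_sizes)]


def generate_de_cohort(
    spec: DECohortSpec,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Generate a two-group cohort matrix with planted DE features.

    Returns
    -------
    matrix : DataFrame [(n_healthy + n_disease) x n_features]
        Raw positive expression values; healthy rows first.
    groups : Series
        ``"healthy"`` / ``"disease"`` per sample.
    truth : DataFrame
        One row per feature with its planted call in {low, normal, high}.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    p = spec.n_features
    n_high = int(round(spec.frac_high * p))
    n_low = int(round(spec.frac_low * p))
    calls = np.full(p, "normal", dtype=object)
    if spec.effect_log2fc > 0:
        order = rng.permutation(p)
        calls[order[:n_high]] = "high"
        calls[order[n_high : n_high + n_low]] = "low"

    baseline = rng.uniform(3.0, 8.0, size=p)
    shift = np.where(calls == "high", spec.effect_log2fc, 0.0) - np.where(
        calls == "low", spec.effect_log2fc, 0.0
    )
    n_total = spec.n_healthy + spec.n_disease
    log2 = np.tile(baseline, (n_total, 1))
    log2[spec.n_healthy :] += shift  # disease rows carry the planted shift
    log2 += spec.noise_sd * rng.standard_normal((n_total, p))

    features = [f"g{j:04d}" for j in range(p)]
    samples = [f"H{i:04d}" for i in range(spec.n_healthy)] + [
        f"D{i:04d}" for i in range(spec.n_disease)
    ]
    matrix = pd.DataFrame(np.exp2(log2), index=samples, columns=features)
    groups = pd.Series(
        ["healthy"] * spec.n_healthy + ["disease"] * spec.n_disease,
        index=samples,
        name="group",
    )
    truth = pd.DataFrame({"feature_id": features, "planted_call": calls})
    return matrix, groups, truth


def _planted_graph_edges(n: int, block: int) -> list[tuple[int, int]]:
    """Cliques over consecutive blocks of ``block`` features."""
    edges: list[tuple[int, int]] = []
    for start in range(0, n, block):
        members = range(start, min(start + block, n))
        edges.extend(
            (p, q) for i, p in enumerate(members) for q in list(members)[i + 1 :]
        )
    return edges


def _draw_pair(
    spec: CanonicalPairSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Raw X, Y draws plus baselines and unit-norm true weights."""
    su = np.asarray(sorted(set(spec.support_u)), dtype=int)
    sv = np.asarray(sorted(set(spec.support_v)), dtype=int)
    base_x = rng.uniform(8.0, 12.0, size=spec.m)
    base_y = rng.uniform(8.0, 12.0, size=spec.n)
    load_u = rng.uniform(0.8, 1.2, size=su.size)
    load_v = rng.uniform(0.8, 1.2, size=sv.size)

    z = rng.standard_normal(spec.s)
    w = spec.latent_corr * z + np.sqrt(1.0 - spec.latent_corr**2) * rng.standard_normal(
        spec.s
    )

    X = base_x + rng.standard_normal((spec.s, spec.m))
    Y = base_y + rng.standard_normal((spec.s, spec.n))
    X[:, su] = (
        base_x[su]
        + np.outer(z, load_u)
        + spec.noise_sd * rng.standard_normal((spec.s, su.size))
    )
    Y[:, sv] = (
        base_y[sv]
        + np.outer(w, load_v)
        + spec.noise_sd * rng.standard_normal((spec.s, sv.size))
    )

    u_star = np.zeros(spec.m)
    u_star[su] = load_u
    u_star /= np.linalg.norm(u_star)
    v_star = np.zeros(spec.n)
    v_star[sv] = load_v
    v_star /= np.linalg.norm(v_star)
    return X, Y, base_x, base_y, u_star, v_star


def generate_canonical_pair(spec: CanonicalPairSpec) -> OmicsDataset:
    """Generate paired matrices sharing one planted sparse canonical pair.

    The returned dataset's ``truth`` dict holds the unit-norm ground-truth
    weights ``u_star``/``v_star``, the supports, and the planted block-graph
    edge list over the Y features.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    X, Y, _, _, u_star, v_star = _draw_pair(spec, rng)

    samples = [f"S{i:04d}" for i in range(spec.s)]
    Xdf = pd.DataFrame(X, index=samples, columns=[f"mrna{j:04d}" for j in range(spec.m)])
    Ydf = pd.DataFrame(Y, index=samples, columns=[f"dnam{j:04d}" for j in range(spec.n)])
    truth = {
        "support_u": sorted(set(spec.support_u)),
        "support_v": sorted(set(spec.support_v)),
        "u_star": u_star,
        "v_star": v_star,
        "latent_corr": spec.latent_corr,
        "graph_edges_v": _planted_graph_edges(spec.n, spec.graph_block_size),
    }
    idx = pd.Index(samples)
    return OmicsDataset(
        X=Xdf,
        Y=Ydf,
        subtype=pd.Series(np.nan, index=idx, name="subtype"),
        group=pd.Series("disease", index=idx, name="group"),
        truth=truth,
    )


def _distinct_sign_patterns(
    rng: np.random.Generator, n_classes: int, width: int
) -> np.ndarray:
    """Random ±1 patterns, redrawn until pairwise distinct."""
    for _ in range(1000):
        pat = rng.choice([-1.0, 1.0], size=(n_classes, width))
        if len({tuple(row) for row in pat}) == n_classes:
            return pat
    raise RuntimeError("could not draw distinct class patterns")  # pragma: no cover


def generate_subtyped_dataset(
    pair: CanonicalPairSpec,
    sub: SubtypeSpec,
    n_healthy: int = 100,
    de_effect_log2fc: float = 2.0,
) -> OmicsDataset:
    """Full pipeline fixture: subtyped disease cohort plus a healthy cohort.

    Disease samples carry the canonical-pair structure of ``pair`` with
    class-conditional mean shifts of magnitude ``sub.class_shift`` (random
    distinct ±1 patterns per class) on both supports, so subtypes are
    predictable from either omics.  Healthy samples express the support
    features at a baseline lower by a factor ``2 ** de_effect_log2fc``, so the
    differential-expression stage retains exactly the support features (up to
    sampling noise).
    """
    pair.validate()
    sub.validate()
    if sum(int(c) for c in sub.class_sizes) != pair.s:
        raise InvalidSpecError(
            f"sum(class_sizes)={sum(sub.class_sizes)} must equal pair.s={pair.s}"
        )
    if n_healthy < 2:
        raise InvalidSpecError("need at least 2 healthy samples")

    rng = np.random.default_rng(np.random.SeedSequence([pair.seed, sub.seed, 7]))
    X, Y, base_x, base_y, u_star, v_star = _draw_pair(pair, rng)
    su = np.asarray(sorted(set(pair.support_u)), dtype=int)
    sv = np.asarray(sorted(set(pair.support_v)), dtype=int)

    names = sub.labels
    y_labels = np.repeat(names, sub.class_sizes)
    perm = rng.permutation(pair.s)
    y_labels = y_labels[perm]

    # One sign pattern per class, shared across omics (truncated to each
    # support's width): subtype-specific methylation shifts are mirrored in
    # expression, so cross-omics support features co-vary across subtypes.
    for _ in range(1000):
        pat = _distinct_sign_patterns(rng, len(names), max(su.size, sv.size))
        pat_x = pat[:, : su.size]
        pat_y = pat[:, : sv.size]
        if (
            len({tuple(r) for r in pat_x}) == len(names)
            and len({tuple(r) for r in pat_y}) == len(names)
        ):
            break
    else:  # pragma: no cover
        raise RuntimeError("could not draw distinct truncated class patterns")
    for c, name in enumerate(names):
        rows = y_labels == name
        X[np.ix_(rows, su)] += sub.class_shift * pat_x[c]
        Y[np.ix_(rows, sv)] += sub.class_shift * pat_y[c]

    # Healthy cohort: support features sit at a reduced baseline so that the
    # disease/healthy fold change on those features is ~2**de_effect_log2fc.
    Xh = base_x + rng.standard_normal((n_healthy, pair.m))
    Yh = base_y + rng.standard_normal((n_healthy, pair.n))
    Xh[:, su] = base_x[su] / 2.0**de_effect_log2fc + pair.noise_sd * rng.standard_normal(
        (n_healthy, su.size)
    )
    Yh[:, sv] = base_y[sv] / 2.0**de_effect_log2fc + pair.noise_sd * rng.standard_normal(
        (n_healthy, sv.size)
    )

    samples = [f"D{i:04d}" for i in range(pair.s)] + [
        f"H{i:04d}" for i in range(n_healthy)
    ]
    idx = pd.Index(samples)
    Xdf = pd.DataFrame(
        np.vstack([X, Xh]), index=idx, columns=[f"mrna{j:04d}" for j in range(pair.m)]
    )
    Ydf = pd.DataFrame(
        np.vstack([Y, Yh]), index=idx, columns=[f"dnam{j:04d}" for j in range(pair.n)]
    )
    subtype = pd.Series(
        list(y_labels) + [np.nan] * n_healthy, index=idx, name="subtype"
    )
    group = pd.Series(
        ["disease"] * pair.s + ["healthy"] * n_healthy, index=idx, name="group"
    )
    de_truth_x = np.where(np.isin(np.arange(pair.m), su), "high", "normal")
    de_truth_y = np.where(np.isin(np.arange(pair.n), sv), "high", "normal")
    truth = {
        "support_u": su.tolist(),
        "support_v": sv.tolist(),
        "u_star": u_star,
        "v_star": v_star,
        "latent_corr": pair.latent_corr,
        "graph_edges_v": _planted_graph_edges(pair.n, pair.graph_block_size),
        "class_patterns_x": pat_x,
        "class_patterns_y": pat_y,
        "de_calls_x": de_truth_x.tolist(),
        "de_calls_y": de_truth_y.tolist(),
        "class_shift": sub.class_shift,
    }
    return OmicsDataset(X=Xdf, Y=Ydf, subtype=subtype, group=group, truth=truth)
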