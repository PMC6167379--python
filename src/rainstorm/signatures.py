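"""De novo mutational-signature discovery with bootstrap stability.

Somatic SNVs are summarised into the standard 96-class trinucleotide
catalog (substitution type x 5' context x 3' context, collapsed to the
pyrimidine reference strand). Non-negative matrix factorisation is run over
bootstrap-resampled catalogs for each candidate signature number n; the
replicate signatures are clustered by cosine distance to yield a stability
score S_n, a consensus factorisation gives the reconstruction error R_n,
and the model with

    n_opt = argmin_n [ (R_n - min R)/(max R - min R)
                       - (S_n - min S)/(max S - min S) ]

is selected. Discovered signatures can be matched greedily (by cosine
similarity) to a reference set such as the COSMIC v2 signatures, and
per-sample exposures compared between groups with a Wilcoxon rank-sum test
under Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.stats import mannwhitneyu
from sklearn.decomposition import NMF
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score
from sklearn.preprocessing import normalize as sk_normalize

from .cohort import MutationRecord, VariantClass
from .stats import bh_adjust

__all__ = [
    "CLASSES_96",
    "MutationCatalog",
    "SignatureSolution",
    "build_catalog",
    "nmf_bootstrap",
    "select_n_opt",
    "match_to_reference",
    "differential_exposure",
    "read_reference_signatures",
]

_SUBS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = "ACGT"
_COMP = str.maketrans("ACGT", "TGCA")

#: The 96 trinucleotide substitution classes in COSMIC order, e.g. "A[C>A]A".
CLASSES_96: list[str] = [
    f"{five}[{sub}]{three}" for sub in _SUBS for five in _BASES for three in _BASES
]
_CLASS_INDEX = {c: i for i, c in enumerate(CLASSES_96)}


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class MutationCatalog:
    """96 x n_samples matrix of SNV counts by trinucleotide class."""

    matrix: np.ndarray
    sample_ids: list[str]
    class_labels: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if self.matrix.shape[0] != 96:
            raise ValueError("catalog must have exactly 96 rows")
        if np.any(self.matrix < 0):
            raise ValueError("catalog counts must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.class_labels, columns=self.sample_ids)


@dataclass
class SignatureSolution:
    """One candidate factorisation: V ~ W H with n signatures."""

    n: int
    W: np.ndarray            # 96 x n, columns sum to 1
    H: np.ndarray            # n x n_samples, >= 0
    recon_error: float       # Frobenius norm of V - WH
    stability: float         # mean cluster cohesion in [0, 1]
    sample_ids: list[str]
    class_labels: list[str]


def classify_snv(ref: str, alt: str, context: str) -> str | None:
    """Map one SNV and its trinucleotide context to a 96-class label.

    ``context`` is the reference trinucleotide centred on the mutated base.
    Purine reference bases are collapsed to the pyrimidine strand by
    reverse-complementing ref, alt and context. Returns None for contexts
    containing N or inconsistent inputs.
    """
    ref, alt, context = ref.upper(), alt.upper(), context.upper()
    if len(context) != 3 or any(b not in _BASES for b in context):
        return None
    if context[1] != ref:
        return None
    if ref in "AG":
        ref, alt, context = (
            ref.translate(_COMP), alt.translate(_COMP), _revcomp(context)
        )
    label = f"{context[0]}[{ref}>{alt}]{context[2]}"
    return label if label in _CLASS_INDEX else None


def build_catalog(records: list[MutationRecord], reference) -> MutationCatalog:
    """Accumulate SNVs into the 96-class catalog per sample.

    ``reference`` is any mapping from chromosome name to an indexable
    sequence (a :class:`pyfaidx.Fasta`, or a plain dict of strings).
    Records whose reference base disagrees with the FASTA, or whose context
    contains N, are skipped with a counted warning.
    """
    samples = sorted({r.patient_id for r in records})
    sidx = {s: i for i, s in enumerate(samples)}
    matrix = np.zeros((96, len(samples)), dtype=np.int64)
    skipped = 0
    for rec in records:
        if rec.variant_class is not VariantClass.SNV:
            continue
        seq = reference[rec.chromosome]
        i = rec.position - 1  # to 0-based
        if i - 1 < 0 or i + 2 > len(seq):
            skipped += 1
            continue
        context = str(seq[i - 1 : i + 2]).upper()
        if context[1:2] != rec.ref_allele.upper():
            skipped += 1
            continue
        label = classify_snv(rec.ref_allele, rec.alt_allele, context)
        if label is None:
            skipped += 1
            continue
        matrix[_CLASS_INDEX[label], sidx[rec.patient_id]] += 1
    if skipped:
        warnings.warn(f"skipped {skipped} SNVs (context N or reference mismatch)")
    return MutationCatalog(matrix=matrix, sample_ids=samples, class_labels=list(CLASSES_96))


def _fit_nmf(V: np.ndarray, n: int, seed: int, max_iter: int = 400) -> np.ndarray:
    """One NMF fit (multiplicative updates, Frobenius loss); returns W.

    Initialisation is the deterministic NNDSVD-A decomposition, so the
    replicate-to-replicate variation probed by the bootstrap comes from the
    resampling alone.
    """
    model = NMF(
        n_components=n,
        init="nndsvda",
        solver="mu",
        beta_loss="frobenius",
        max_iter=max_iter,
        tol=1e-4,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        W = model.fit_transform(V)
    return W


def _refit_H(V: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Exposures for fixed W by per-sample non-negative least squares."""
    H = np.empty((W.shape[1], V.shape[1]))
    for j in range(V.shape[1]):
        H[:, j], _ = nnls(W, V[:, j])
    return H


def nmf_bootstrap(
    catalog: MutationCatalog,
    n: int,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> SignatureSolution:
    """Bootstrap-NMF solution for one candidate signature count.

    Each replicate resamples every sample's mutations (a multinomial draw on
    its catalog column at the observed total) and factorises the resampled
    catalog. The pooled replicate signatures are partitioned into n clusters
    by cosine distance; stability S_n is the mean silhouette of that
    clustering (clipped at 0), the consensus W collects the cluster medoids
    (renormalised to column sum 1) and H is refit on the original catalog
    with W fixed. The reconstruction error R_n is ||V - WH||_F.
    """
    V = catalog.matrix.astype(float)
    if not V.sum():
        raise ValueError("catalog is all zero")
    if n < 1 or n > min(96, catalog.n_samples):
        raise ValueError(f"invalid signature count n={n}")
    if n_bootstrap < 2:
        raise ValueError("need at least 2 bootstrap replicates")

    ss = np.random.SeedSequence([seed, n])
    rng = np.random.default_rng(ss)
    fit_seeds = ss.spawn(n_bootstrap)
    totals = V.sum(axis=0)
    probs = V / np.where(totals > 0, totals, 1.0)

    reps = []
    for r in range(n_bootstrap):
        Vb = np.column_stack(
            [
                rng.multinomial(int(totals[j]), probs[:, j])
                if totals[j] > 0
                else np.zeros(96)
                for j in range(V.shape[1])
            ]
        ).astype(float)
        W = _fit_nmf(Vb, n, seed=int(fit_seeds[r].generate_state(1)[0] % (2**31)))
        colsum = W.sum(axis=0)
        keep = colsum > 0
        reps.append(W[:, keep] / colsum[keep])
    X = np.column_stack(reps).T  # (replicate signatures) x 96

    Xn = sk_normalize(X)  # unit L2: Euclidean k-means approximates cosine
    if n == 1:
        medoid_idx = [int(np.argmax(Xn @ Xn.mean(axis=0)))]
        cohesion = float(np.mean(Xn @ Xn[medoid_idx[0]]))
        stability = float(np.clip(cohesion, 0.0, 1.0))
    else:
        km = KMeans(n_clusters=n, n_init=10, random_state=int(seed) % (2**31))
        labels = km.fit_predict(Xn)
        if len(np.unique(labels)) < 2:
            stability = 0.0
        else:
            stability = float(
                np.clip(silhouette_score(Xn, labels, metric="cosine"), 0.0, 1.0)
            )
        medoid_idx = []
        for c in range(n):
            members = np.where(labels == c)[0]
            if not len(members):
                continue
            sims = Xn[members] @ Xn[members].T
            medoid_idx.append(int(members[np.argmax(sims.sum(axis=1))]))
    W = X[medoid_idx].T
    W = W / W.sum(axis=0)
    if W.shape[1] < n:  # an empty cluster: pad with uniform columns
        pad = np.full((96, n - W.shape[1]), 1.0 / 96)
        W = np.column_stack([W, pad])
    # Polish the consensus on the original catalog: a short NMF refinement
    # initialised at the medoids removes single-replicate sampling noise
    # and keeps the reconstruction error non-increasing in n.
    H0 = np.maximum(_refit_H(V, W), 1e-10)
    model = NMF(
        n_components=n, init="custom", solver="mu", beta_loss="frobenius",
        max_iter=400, tol=1e-5,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        Wp = model.fit_transform(V, W=np.maximum(W, 1e-10), H=H0)
    colsum = Wp.sum(axis=0)
    if np.all(colsum > 0):
        W = Wp / colsum
    H = _refit_H(V, W)
    recon = float(np.linalg.norm(V - W @ H))
    return SignatureSolution(
        n=n,
        W=W,
        H=H,
        recon_error=recon,
        stability=stability,
        sample_ids=list(catalog.sample_ids),
        class_labels=list(catalog.class_labels),
    )


def select_n_opt(solutions: list[SignatureSolution]) -> SignatureSolution:
    """Pick the solution minimising normalised error minus normalised
    stability; ties break toward the smaller n."""
    if not solutions:
        raise ValueError("no candidate solutions")
    sols = sorted(solutions, key=lambda s: s.n)
    R = np.array([s.recon_error for s in sols], dtype=float)
    S = np.array([s.stability for s in sols], dtype=float)

    def norm(v: np.ndarray) -> np.ndarray:
        rng_ = v.max() - v.min()
        if rng_ == 0:
            return np.zeros_like(v)
        return (v - v.min()) / rng_

    score = norm(R) - norm(S)
    return sols[int(np.argmin(score))]


def match_to_reference(
    W: np.ndarray,
    reference: pd.DataFrame,
    discovered_names: list[str] | None = None,
) -> pd.DataFrame:
    """Greedy one-to-one assignment of discovered signatures to a reference.

    ``reference`` is a 96 x m DataFrame (rows aligned to CLASSES_96 order,
    one column per named reference signature). The globally most similar
    (discovered, reference) pair is assigned first, both are removed, and
    the process repeats; with fewer reference than discovered signatures the
    leftovers are labelled "unassigned". Ties resolve to the first pair in
    (discovered, reference) order.
    """
    W = np.asarray(W, dtype=float)
    ref = reference.to_numpy(dtype=float)
    names = list(reference.columns)
    n, m = W.shape[1], ref.shape[1]

    def unit(M):
        norms = np.linalg.norm(M, axis=0)
        return M / np.where(norms > 0, norms, 1.0)

    sim = unit(W).T @ unit(ref)  # n x m cosine similarities
    assigned: dict[int, tuple[str, float]] = {}
    free_d = list(range(n))
    free_r = list(range(m))
    while free_d and free_r:
        sub = sim[np.ix_(free_d, free_r)]
        flat = int(np.argmax(sub))
        di, rj = divmod(flat, len(free_r))
        d, r = free_d[di], free_r[rj]
        assigned[d] = (names[r], float(sim[d, r]))
        free_d.remove(d)
        free_r.remove(r)
    rows = []
    dnames = discovered_names or [f"V{i + 1}" for i in range(n)]
    for d in range(n):
        name, simval = assigned.get(d, ("unassigned", np.nan))
        rows.append({"discovered": dnames[d], "reference": name, "cosine": simval})
    return pd.DataFrame(rows)


def differential_exposure(
    H: np.ndarray,
    groups: list[str] | np.ndarray,
    normalize: bool = True,
    signature_names: list[str] | None = None,
) -> pd.DataFrame:
    """Wilcoxon rank-sum comparison of per-sample exposures between two
    groups, with Benjamini-Hochberg q-values across signatures.

    ``normalize`` converts exposures to per-sample proportions (relative
    exposures) before testing, which is the default comparison.
    """
    H = np.asarray(H, dtype=float)
    groups = np.asarray(groups)
    levels = sorted(pd.unique(groups).tolist())
    if len(levels) != 2:
        raise ValueError(f"need exactly two group labels, got {levels}")
    a_mask = groups == levels[0]
    b_mask = groups == levels[1]
    if a_mask.sum() < 2 or b_mask.sum() < 2:
        warnings.warn("a group has fewer than 2 samples; the exact test is weak")
    X = H.copy()
    if normalize:
        colsum = X.sum(axis=0)
        X = X / np.where(colsum > 0, colsum, 1.0)
    pvals, stats_ = [], []
    for i in range(X.shape[0]):
        a, b = X[i, a_mask], X[i, b_mask]
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            stat, p = np.nan, 1.0
        else:
            stat, p = mannwhitneyu(a, b, alternative="two-sided", method="auto")
        pvals.append(float(p))
        stats_.append(float(stat) if stat == stat else np.nan)
    qvals = bh_adjust(pvals)
    names = signature_names or [f"V{i + 1}" for i in range(X.shape[0])]
    return pd.DataFrame(
        {
            "signature": names,
            "statistic": stats_,
            "p": pvals,
            "q": qvals,
            f"median_{levels[0]}": np.median(X[:, a_mask], axis=1),
            f"median_{levels[1]}": np.median(X[:, b_mask], axis=1),
        }
    )


def read_reference_signatures(path: str) -> pd.DataFrame:
    """Read a reference signature matrix: TSV with the class label in the
    first column (A[C>T]G notation) and one column per signature."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = [c for c in CLASSES_96 if c not in df.index]
    if missing:
        raise ValueError(f"reference signatures missing classes, e.g. {missing[:3]}")
    return df.loc[CLASSES_96]
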