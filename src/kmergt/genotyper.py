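"""Empirical-Bayes negative-binomial genotype calling from k-mer counts.

Model
-----
For one individual, the count of a k-mer carried by ``c`` allele copies is
modeled as negative binomial with mean ``mu(c) = epsilon + c * lambda_ / 2``
and variance ``mu (1 + alpha * mu)`` (``alpha0`` replaces ``alpha`` for the
0-copy distribution, whose counts come only from sequencing-error leakage
``epsilon``).  ``lambda_`` is the individual's mean depth per locus, so one
allele copy contributes ``lambda_/2``.  A genotype is a pair of allele copy
numbers ``(cA, cB)`` with ``cA + cB <= 4``: besides the canonical diploid
classes AA=(2,0), AB=(1,1), BB=(0,2) (prior weights ``pi_AA``, ``pi_AB``,
``pi_BB``) the model admits mono-, tri- and tetra-allelic classes that share
the remaining prior mass ``pi_NC`` uniformly -- these correspond to
deletions and duplications and are reported as NC ("no call") by default.
The eight scalars (lambda_, alpha, epsilon, alpha0 and the prior simplex)
are estimated from the individual's own counts at up to 100,000 autosomal
markers by expectation-maximization, which is what makes the Bayes
classifier *empirical*.

Combining a marker's k-mer pairs
--------------------------------
A marker carries up to three k-mer pairs, but all of them overlap the same
variant base and are counted from the same sequencing reads: one read
covering the SNV typically increments every pair at once, so the per-pair
counts are near-duplicate observations rather than independent ones.
Multiplying per-pair likelihoods would therefore triple the evidence of a
single read.  The classifier instead reduces the pairs to one effective
observation per allele -- the rounded median of the per-pair counts, which
is also robust to the loss of a single k-mer through a rare neighboring
mutation -- and evaluates the model on that.  A ``pair_agreement`` flag
records whether each pair, taken alone, supports the same class.
:func:`genotype_log_likelihood` itself scores any set of pair observations
as conditionally independent, which is exact for the single effective
observation the caller feeds it.

The haploid model (male chrX/chrY) uses the same machinery with canonical
single-copy classes A=(1,0), B=(0,1); the diploid heterozygote prior mass
is reassigned to the non-canonical pool.  Sex is inferred from the ratio of
median chrX marker depth to median autosomal depth (about 0.5 for males,
1.0 for females).
"""

from __future__ import annotations

import logging
import warnings
from collections.abc import Sequence
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp, xlogy

from .kmercount import CountTable
from .variantdb import AUTOSOME, CHRX, CHRY, MarkerRecord

logger = logging.getLogger(__name__)

MAX_COPIES = 4
#: all copy-number classes (cA, cB) with cA + cB <= 4, in a fixed order
CLASSES: tuple[tuple[int, int], ...] = tuple(
    (t - cb, cb) for t in range(MAX_COPIES + 1) for cb in range(t + 1))
_CA = np.array([c[0] for c in CLASSES])
_CB = np.array([c[1] for c in CLASSES])
N_CLASSES = len(CLASSES)

_DIPLOID_CANON = {(2, 0): "AA", (1, 1): "AB", (0, 2): "BB"}
_HAPLOID_CANON = {(1, 0): "A", (0, 1): "B"}

_PRIOR_FLOOR = 1e-10


@dataclass(frozen=True)
class ModelParams:
    """The eight-parameter per-individual negative-binomial genotype model."""

    lambda_: float   # mean depth of coverage per locus
    alpha: float     # overdispersion for copy >= 1:  var = mu (1 + alpha mu)
    epsilon: float   # mean spurious count of a 0-copy allele
    alpha0: float    # overdispersion of the 0-copy distribution
    pi_AA: float
    pi_AB: float
    pi_BB: float
    pi_NC: float     # total prior mass of all non-canonical classes

    def __post_init__(self):
        if self.lambda_ <= 0:
            raise ValueError(f"lambda_ must be > 0, got {self.lambda_}")
        if self.alpha < 0 or self.alpha0 < 0 or self.epsilon < 0:
            raise ValueError("alpha, alpha0 and epsilon must be >= 0")
        pis = (self.pi_AA, self.pi_AB, self.pi_BB, self.pi_NC)
        if min(pis) < 0 or abs(sum(pis) - 1.0) > 1e-6:
            raise ValueError(f"class priors must be >= 0 and sum to 1, "
                             f"got {pis}")

    def save(self, path) -> None:
        """Write as a small key=value text file (re-usable across runs)."""
        with open(path, "w", newline="\n") as fh:
            for name in ("lambda_", "alpha", "epsilon", "alpha0",
                         "pi_AA", "pi_AB", "pi_BB", "pi_NC"):
                fh.write(f"{name}={getattr(self, name):.10g}\n")

    @classmethod
    def load(cls, path) -> "ModelParams":
        values = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, val = line.partition("=")
                values[key.strip()] = float(val)
        return cls(**values)


@dataclass(frozen=True)
class GenotypeCall:
    """MAP copy-number call for one marker."""

    marker_id: str
    cA: int
    cB: int
    posterior: float
    label: str  # AA/AB/BB (diploid), A/B (haploid), or NC
    per_pair_agreement: bool


@dataclass(frozen=True)
class SexCall:
    sex: str          # "male" | "female"
    chrx_ratio: float  # median chrX depth / median autosomal depth


# ---------------------------------------------------------------------------
# negative binomial pmf


def nb_log_pmf(x, mu: float, alpha: float):
    """Log pmf of the NB distribution with mean mu, var mu(1 + alpha mu).

    Size/shape parameterization: r = 1/alpha, p = r / (r + mu); the
    alpha -> 0 limit is the Poisson pmf, and mu == 0 is a point mass at 0.
    Accepts scalar or array x (non-negative integers).
    """
    x_arr = np.asarray(x)
    if (x_arr < 0).any():
        raise ValueError("counts must be >= 0")
    scalar = np.isscalar(x) or x_arr.ndim == 0
    x_arr = np.atleast_1d(x_arr).astype(np.float64)
    if mu < 0 or alpha < 0:
        raise ValueError("mu and alpha must be >= 0")
    if mu == 0:
        out = np.where(x_arr == 0, 0.0, -np.inf)
    elif alpha == 0:
        out = xlogy(x_arr, mu) - mu - gammaln(x_arr + 1)
    else:
        r = 1.0 / alpha
        out = (gammaln(x_arr + r) - gammaln(r) - gammaln(x_arr + 1)
               + r * np.log(r / (r + mu)) + x_arr * np.log(mu / (r + mu)))
    return float(out[0]) if scalar else out


def _log_pmf_tables(params: ModelParams, xmax: int) -> np.ndarray:
    """(5, xmax+1) table of nb_log_pmf(x; mu(c), alpha(c)) for c = 0..4."""
    xs = np.arange(xmax + 1)
    out = np.empty((MAX_COPIES + 1, xmax + 1))
    for c in range(MAX_COPIES + 1):
        mu = params.epsilon + c * params.lambda_ / 2.0
        alpha = params.alpha0 if c == 0 else params.alpha
        out[c] = nb_log_pmf(xs, mu, alpha)
    return out


def genotype_log_likelihood(counts: Sequence[tuple[int, int]],
                            cA: int, cB: int,
                            params: ModelParams) -> float:
    """Joint log-likelihood of pair observations given copy numbers.

    The observations are scored as conditionally independent given the
    genotype; the classifier feeds this a single effective observation per
    marker (see module docstring).
    """
    if len(counts) == 0:
        raise ValueError("empty count list")
    if cA < 0 or cB < 0 or cA + cB > MAX_COPIES:
        raise ValueError(f"copy numbers out of range: ({cA}, {cB})")
    mu_a = params.epsilon + cA * params.lambda_ / 2.0
    mu_b = params.epsilon + cB * params.lambda_ / 2.0
    al_a = params.alpha0 if cA == 0 else params.alpha
    al_b = params.alpha0 if cB == 0 else params.alpha
    total = 0.0
    for r, a in counts:
        total += nb_log_pmf(r, mu_a, al_a) + nb_log_pmf(a, mu_b, al_b)
    return float(total)


# ---------------------------------------------------------------------------
# priors and posteriors


def class_log_priors(params: ModelParams, ploidy_model: str) -> np.ndarray:
    """Log prior over the 15 copy-number classes for one ploidy model."""
    pi = np.empty(N_CLASSES)
    if ploidy_model == "diploid":
        pi.fill(params.pi_NC / (N_CLASSES - 3))
        pi[CLASSES.index((2, 0))] = params.pi_AA
        pi[CLASSES.index((1, 1))] = params.pi_AB
        pi[CLASSES.index((0, 2))] = params.pi_BB
    elif ploidy_model == "haploid":
        # heterozygote mass has nowhere to go in a haploid genome
        pi.fill((params.pi_NC + params.pi_AB) / (N_CLASSES - 2))
        pi[CLASSES.index((1, 0))] = params.pi_AA
        pi[CLASSES.index((0, 1))] = params.pi_BB
    else:
        raise ValueError(f"unknown ploidy model {ploidy_model!r}")
    with np.errstate(divide="ignore"):
        return np.log(pi)


def effective_counts(table: CountTable) -> np.ndarray:
    """(n, 2) rounded median of per-pair (ref, alt) counts per marker."""
    n = len(table)
    out = np.zeros((n, 2), dtype=np.int64)
    for npair in np.unique(table.npairs):
        mask = table.npairs == npair
        med = np.median(table.counts[mask][:, :npair, :], axis=1)
        out[mask] = np.floor(med + 0.5).astype(np.int64)
    return out


def _posterior_matrix(xr: np.ndarray, xa: np.ndarray, params: ModelParams,
                      ploidy_model: str) -> np.ndarray:
    """(n, 15) posterior over copy-number classes for effective counts."""
    xmax = int(max(xr.max(initial=0), xa.max(initial=0)))
    tab = _log_pmf_tables(params, xmax)
    lr = tab[:, xr]  # (5, n)
    la = tab[:, xa]
    logp = class_log_priors(params, ploidy_model)
    ll = lr[_CA].T + la[_CB].T + logp  # (n, 15)
    ll -= logsumexp(ll, axis=1, keepdims=True)
    return np.exp(ll)


def _canonical_label(cA: int, cB: int, ploidy_model: str) -> str:
    table = _DIPLOID_CANON if ploidy_model == "diploid" else _HAPLOID_CANON
    return table.get((cA, cB), "NC")


def call_genotype(counts: Sequence[tuple[int, int]], params: ModelParams,
                  ploidy_model: str = "diploid",
                  marker_id: str = "") -> GenotypeCall:
    """MAP copy-number genotype from the pair counts of one marker.

    The pairs are reduced to one effective (ref, alt) observation (rounded
    median); Bayes' rule over all 15 copy-number classes gives the MAP
    class and its normalized posterior.  ``per_pair_agreement`` is True iff
    every pair's individually-MAP class matches the joint call.
    """
    if len(counts) == 0:
        raise ValueError("empty count list")
    arr = np.asarray(counts, dtype=np.int64).reshape(-1, 2)
    med = np.floor(np.median(arr, axis=0) + 0.5).astype(np.int64)
    post = _posterior_matrix(med[:1], med[1:], params, ploidy_model)[0]
    best = int(np.argmax(post))
    cA, cB = CLASSES[best]

    agree = True
    if arr.shape[0] > 1:
        pp = _posterior_matrix(arr[:, 0], arr[:, 1], params, ploidy_model)
        agree = bool((np.argmax(pp, axis=1) == best).all())
    return GenotypeCall(marker_id, cA, cB, float(post[best]),
                        _canonical_label(cA, cB, ploidy_model), agree)


# ---------------------------------------------------------------------------
# parameter estimation (EM)


_DEFAULT_INIT = dict(epsilon=0.1, alpha=0.05, alpha0=0.05,
                     priors=(0.6, 0.2, 0.1, 0.1))


def estimate_params(count_table: CountTable, seed: int | None = None,
                    max_markers: int = 100_000, min_markers: int = 1_000,
                    tol: float = 1e-6, max_iter: int = 200,
                    ploidy_model: str = "diploid",
                    init: ModelParams | None = None) -> ModelParams:
    """Fit the eight-parameter model to one individual's counts by EM.

    The E-step assigns copy-number-class responsibilities under the current
    parameters; the M-step re-estimates lambda_, epsilon, alpha and alpha0
    by responsibility-weighted moments and the priors by mean
    responsibilities.  Initialization: lambda_ = median marker depth,
    epsilon = 0.1, alpha = alpha0 = 0.05, priors (0.6, 0.2, 0.1, 0.1).
    Stops when the largest relative parameter change drops below ``tol`` or
    after ``max_iter`` iterations.  Deterministic given the input and
    ``seed`` (used only when subsampling to ``max_markers``).

    The caller is expected to pass autosomal markers for the diploid model
    and chrX markers for the haploid one.
    """
    x = effective_counts(count_table)
    nonzero = int((x.sum(axis=1) > 0).sum())
    if nonzero < min_markers:
        raise ValueError(
            f"only {nonzero} markers with nonzero counts "
            f"(>= {min_markers} required); sequence to higher coverage or "
            "supply more markers")
    if len(x) > max_markers:
        rng = np.random.default_rng(seed)
        keep = rng.choice(len(x), size=max_markers, replace=False)
        keep.sort()
        x = x[keep]
    xr, xa = x[:, 0], x[:, 1]

    if init is None:
        lam0 = float(np.median(xr + xa))
        if lam0 <= 0:
            lam0 = max(float(np.mean(xr + xa)), 0.5)
        d = _DEFAULT_INIT
        params = ModelParams(lam0, d["alpha"], d["epsilon"], d["alpha0"],
                             *d["priors"])
    else:
        params = init

    is0 = (_CA == 0), (_CB == 0)
    for _ in range(max_iter):
        w = _posterior_matrix(xr, xa, params, ploidy_model)  # (n, 15)

        # responsibility-weighted moment updates
        w_r0 = w[:, is0[0]].sum(axis=1)
        w_a0 = w[:, is0[1]].sum(axis=1)
        den0 = w_r0.sum() + w_a0.sum()
        eps = float((w_r0 @ xr + w_a0 @ xa) / den0) if den0 > 0 else 0.0
        eps = max(eps, 1e-6)

        wr_c = w @ _CA
        wa_c = w @ _CB
        lam_den = float((w * (_CA ** 2 + _CB ** 2)).sum())
        lam_num = float(wr_c @ (xr - eps) + wa_c @ (xa - eps))
        lam = max(2.0 * lam_num / lam_den, 1e-3) if lam_den > 0 \
            else params.lambda_

        a_num = a_den = a0_num = a0_den = 0.0
        for c in range(MAX_COPIES + 1):
            mu = eps + c * lam / 2.0
            wc_r = w[:, _CA == c].sum(axis=1)
            wc_a = w[:, _CB == c].sum(axis=1)
            num = float(wc_r @ ((xr - mu) ** 2 - mu)
                        + wc_a @ ((xa - mu) ** 2 - mu))
            den = float((wc_r.sum() + wc_a.sum()) * mu * mu)
            if c == 0:
                a0_num, a0_den = num, den
            else:
                a_num += num
                a_den += den
        alpha = float(np.clip(a_num / a_den, 0.0, 10.0)) if a_den > 0 else 0.0
        alpha0 = float(np.clip(a0_num / a0_den, 0.0, 100.0)) \
            if a0_den > 0 else 0.0

        means = w.mean(axis=0)
        if ploidy_model == "diploid":
            p_aa = means[CLASSES.index((2, 0))]
            p_ab = means[CLASSES.index((1, 1))]
            p_bb = means[CLASSES.index((0, 2))]
        else:
            p_aa = means[CLASSES.index((1, 0))]
            p_ab = 0.0
            p_bb = means[CLASSES.index((0, 1))]
        pis = np.maximum([p_aa, p_ab, p_bb], _PRIOR_FLOOR)
        p_nc = max(1.0 - pis.sum(), _PRIOR_FLOOR)
        total = pis.sum() + p_nc

        new = ModelParams(lam, alpha, eps, alpha0,
                          float(pis[0] / total), float(pis[1] / total),
                          float(pis[2] / total), float(p_nc / total))
        old_vec = np.array([params.lambda_, params.alpha, params.epsilon,
                            params.alpha0, params.pi_AA, params.pi_AB,
                            params.pi_BB, params.pi_NC])
        new_vec = np.array([new.lambda_, new.alpha, new.epsilon, new.alpha0,
                            new.pi_AA, new.pi_AB, new.pi_BB, new.pi_NC])
        rel = np.abs(new_vec - old_vec) / np.maximum(np.abs(old_vec), 1e-8)
        params = new
        if rel.max() < tol:
            break
    return params


def fit_haploid_model(count_table: CountTable,
                      diploid_params: ModelParams,
                      sex: str = "male", **kwargs) -> ModelParams:
    """Fit the single-copy model on chrX markers of a male individual.

    Uses the same EM machinery with haploid canonical classes; the
    per-copy mean (lambda_/2) is expected to match the diploid fit.
    """
    if sex != "male":
        raise ValueError("the haploid model is fitted for males only")
    init = replace(diploid_params,
                   pi_AA=diploid_params.pi_AA + diploid_params.pi_AB / 2,
                   pi_AB=0.0,
                   pi_BB=diploid_params.pi_BB + diploid_params.pi_AB / 2)
    return estimate_params(count_table, ploidy_model="haploid", init=init,
                           **kwargs)


# ---------------------------------------------------------------------------
# sex inference


def detect_sex(count_table: CountTable,
               marker_chrom_classes: Sequence[str],
               threshold: float = 0.7) -> SexCall:
    """Infer sex from the chrX / autosome ratio of median marker depths.

    One X copy (male) halves chrX depth, so the ratio sits near 0.5 for
    males and 1.0 for females; the decision threshold is the midpoint 0.7.
    Requires >= 100 chrX and >= 100 autosomal markers with counts.
    """
    classes = np.asarray(marker_chrom_classes)
    if len(classes) != len(count_table):
        raise ValueError("chrom classes must align with the count table")
    depth = effective_counts(count_table).sum(axis=1)
    x_depth = depth[classes == CHRX]
    a_depth = depth[classes == AUTOSOME]
    if len(x_depth) < 100:
        raise ValueError(f"too few chrX markers for sex detection "
                         f"({len(x_depth)} < 100)")
    if len(a_depth) < 100:
        raise ValueError(f"too few autosomal markers for sex detection "
                         f"({len(a_depth)} < 100)")
    med_a = float(np.median(a_depth))
    if med_a <= 0:
        raise ValueError("median autosomal depth is zero; cannot infer sex")
    ratio = float(np.median(x_depth)) / med_a
    if 0.65 <= ratio <= 0.75:
        warnings.warn(f"ambiguous chrX depth ratio {ratio:.3f} "
                      "(expected ~0.5 male / ~1.0 female)", stacklevel=2)
    return SexCall("male" if ratio < threshold else "female", ratio)


# ---------------------------------------------------------------------------
# calling every marker


def call_all(count_table: CountTable, markers: Sequence[MarkerRecord],
             params: ModelParams, sex: str,
             haploid_params: ModelParams | None = None,
             output_mode: str = "default",
             min_posterior: float | None = None) -> pd.DataFrame:
    """Genotype every marker of an individual.

    Autosomal (and female chrX) markers use the diploid model; male
    chrX/chrY markers use the haploid one (``haploid_params`` when given,
    else the diploid parameters with haploid class structure).  chrY rows
    are omitted entirely for females.  Default mode reports canonical
    labels or NC; full mode adds copy numbers, the MAP posterior, the
    per-pair agreement flag and all 15 class posteriors.  Deterministic
    given its inputs.
    """
    if output_mode not in ("default", "full"):
        raise ValueError(f"unknown output mode {output_mode!r}")
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    if len(markers) != len(count_table) or any(
            m.variant.id != vid
            for m, vid in zip(markers, count_table.ids)):
        raise ValueError("count table does not match the marker database")

    classes = np.array([m.variant.chrom_class for m in markers])
    keep = np.ones(len(markers), dtype=bool)
    if sex == "female":
        keep &= classes != CHRY
    haploid = np.zeros(len(markers), dtype=bool)
    if sex == "male":
        haploid = (classes == CHRX) | (classes == CHRY)

    x = effective_counts(count_table)
    post = np.zeros((len(markers), N_CLASSES))
    for model, mask in (("diploid", keep & ~haploid),
                        ("haploid", keep & haploid)):
        if not mask.any():
            continue
        p = params
        if model == "haploid" and haploid_params is not None:
            p = haploid_params
        post[mask] = _posterior_matrix(x[mask, 0], x[mask, 1], p, model)

    best = np.argmax(post, axis=1)
    map_post = post[np.arange(len(markers)), best]

    # per-pair agreement: each pair alone must pick the joint MAP class
    agree = np.ones(len(markers), dtype=bool)
    for model, model_mask in (("diploid", keep & ~haploid),
                              ("haploid", keep & haploid)):
        p = params
        if model == "haploid" and haploid_params is not None:
            p = haploid_params
        for j in range(int(count_table.npairs.max(initial=0))):
            mask = model_mask & (count_table.npairs > max(j, 1))
            if not mask.any():
                continue
            pp = _posterior_matrix(count_table.counts[mask, j, 0],
                                   count_table.counts[mask, j, 1], p, model)
            agree[mask] &= np.argmax(pp, axis=1) == best[mask]

    rows = []
    for i, m in enumerate(markers):
        if not keep[i]:
            continue
        model = "haploid" if haploid[i] else "diploid"
        cA, cB = CLASSES[best[i]]
        label = _canonical_label(cA, cB, model)
        if min_posterior is not None and map_post[i] < min_posterior:
            label = "NC"
        v = m.variant
        row = {"id": v.id, "chrom": v.chrom, "pos": v.pos,
               "ref": v.ref, "alt": v.alt, "label": label}
        if output_mode == "full":
            row.update(cA=cA, cB=cB, posterior=map_post[i],
                       pair_agreement=agree[i])
            for ci, (a, b) in enumerate(CLASSES):
                row[f"p_{a}{b}"] = post[i, ci]
        rows.append(row)
    return pd.DataFrame(rows)


def write_calls(calls: pd.DataFrame, path) -> None:
    calls.to_csv(path, sep="\t", index=False, lineterminator="\n",
                 float_format="%.6g")


def read_calls(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
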