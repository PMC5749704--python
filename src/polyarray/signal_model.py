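"""Contrast/size transformation and mixture-model genotype calling.

Axiom-style arrays measure two channel intensities per probeset and sample
(one per allele).  Calling works in a transformed space::

    contrast = log2((a*100 + 100) / (b*100 + 100))
    size     = [log2(a*100 + 100) + log2(b*100 + 100)] / 2

where ``a`` and ``b`` are the A- and B-allele signals.  In this space an
ordinary biallelic probeset produces up to three clusters along the contrast
axis (BB < AB < AA), and a probeset whose target sequence is deleted in some
accessions (an off-target variant, OTV) shows a fourth cluster at markedly
lower size — the null allele.

Genotypes are called per probeset with a diagonal-covariance 2-D Gaussian
mixture fitted by EM; the number of genotype components (1–3) is chosen by
BIC.  Inbred material carries very few true heterozygotes, so the AB
component's prior weight is down-weighted by ``2**-penalty`` (the "inbred
penalty"); the production protocol runs calling twice, first with a mild
penalty of 4, then reprocessing probesets that failed QC ("Other" and
"NoMinorHom") with a strong penalty of 16.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import logsumexp

CALL_AA = "AA"
CALL_AB = "AB"
CALL_BB = "BB"
CALL_OO = "OO"  # null allele (off-target variant)
CALL_NN = "NN"  # missing / no-call

GENOTYPE_LABELS = (CALL_BB, CALL_AB, CALL_AA)

_VAR_FLOOR = 1e-6
_DEGENERATE_SPREAD = 1e-9


def to_contrast_size(signal_a, signal_b):
    """Transform two-channel signals into (contrast, size).

    Parameters
    ----------
    signal_a, signal_b : array-like of non-negative floats
        Raw allele-channel intensities.  NaN marks a missing measurement and
        propagates to NaN output.

    Returns
    -------
    (contrast, size) : ndarray pair
        ``contrast = log2((a*100+100)/(b*100+100))`` and
        ``size = [log2(a*100+100) + log2(b*100+100)] / 2``.  The +100 offset
        keeps both finite for any non-negative input.
    """
    a = np.asarray(signal_a, dtype=float)
    b = np.asarray(signal_b, dtype=float)
    for name, x in (("signal_a", a), ("signal_b", b)):
        bad = np.isinf(x) | (~np.isnan(x) & (x < 0))
        if np.any(bad):
            raise ValueError(f"{name} must be non-negative and finite (NaN = missing)")
    la = np.log2(a * 100.0 + 100.0)
    lb = np.log2(b * 100.0 + 100.0)
    return la - lb, (la + lb) / 2.0


def contrast_size_to_signals(contrast, size):
    """Invert :func:`to_contrast_size`.

    Solves ``log2(a*100+100) = size + contrast/2`` (and the mirror equation
    for ``b``), so the round trip through :func:`to_contrast_size` is exact
    up to floating point.  Requires ``size - |contrast|/2 >= log2(100)`` for
    non-negative signals.
    """
    c = np.asarray(contrast, dtype=float)
    s = np.asarray(size, dtype=float)
    a = (np.exp2(s + c / 2.0) - 100.0) / 100.0
    b = (np.exp2(s - c / 2.0) - 100.0) / 100.0
    if np.any((a < 0) | (b < 0)):
        raise ValueError("contrast/size pair maps to a negative signal; size too small")
    return a, b


@dataclass
class ProbesetModel:
    """Fitted per-probeset cluster model in (contrast, size) space.

    ``means``/``variances`` are (k, 2) arrays over the dimensions
    (contrast, size); ``weights`` the mixing proportions; ``labels`` the
    genotype label of each component (subset of BB/AB/AA plus at most one
    OTV).  ``counts`` are responsibility masses (soft membership counts).
    """

    means: np.ndarray
    variances: np.ndarray
    weights: np.ndarray
    labels: list
    inbred_penalty: float = 0.0
    converged: bool = True
    log_likelihood: float = np.nan
    n_points: int = 0
    counts: np.ndarray = field(default_factory=lambda: np.zeros(0))
    degenerate: bool = False
    ll_history: list = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return len(self.labels)

    @property
    def has_otv(self) -> bool:
        return "OTV" in self.labels

    def component(self, label: str) -> int:
        return self.labels.index(label)

    def log_responsibilities(self, contrast, size):
        """Per-point log posterior over components; rows are points."""
        x = np.column_stack([np.asarray(contrast, float), np.asarray(size, float)])
        joint = _log_density(x, self.means, self.variances) + np.log(self.weights)
        return joint - logsumexp(joint, axis=1, keepdims=True)


def _log_density(x, means, variances):
    k = means.shape[0]
    out = np.empty((x.shape[0], k))
    for j in range(k):
        d = x - means[j]
        out[:, j] = -0.5 * np.sum(d * d / variances[j], axis=1) - 0.5 * np.sum(
            np.log(2.0 * np.pi * variances[j])
        )
    return out


def _penalized_weights(raw, labels, penalty):
    w = np.asarray(raw, dtype=float).copy()
    for k, lab in enumerate(labels):
        if lab == CALL_AB:
            w[k] *= 2.0 ** (-penalty)
    return w / w.sum()


def _assign_labels(contrast_means) -> list:
    """Label components sorted by contrast.

    Three components map to BB/AB/AA directly.  With two, clusters flanking
    zero read as BB/AA; two clusters on the same side of zero read as the
    inner one being AB (the classic "no minor homozygote" geometry).  A
    single component is AA or BB by the sign of its contrast.
    """
    k = len(contrast_means)
    if k == 3:
        return [CALL_BB, CALL_AB, CALL_AA]
    if k == 2:
        lo, hi = contrast_means
        if lo < 0.0 <= hi:
            return [CALL_BB, CALL_AA]
        if lo >= 0.0:  # both on the positive side
            return [CALL_AB, CALL_AA]
        return [CALL_BB, CALL_AB]  # both on the negative side
    return [CALL_AA if contrast_means[0] >= 0 else CALL_BB]


def _fit_k(x, k, penalty, max_iter, tol):
    """EM for a k-component diagonal-Gaussian mixture, quantile-initialised.

    Labels are assigned from the initial contrast ordering so the inbred
    penalty can act on the AB component during fitting; components with
    posterior mass below 1/(2n) are pruned.  Returns None if the fit
    collapses below k=1.
    """
    n = x.shape[0]
    order = np.argsort(x[:, 0], kind="stable")
    groups = [g for g in np.array_split(order, k) if len(g) > 0]
    means = np.vstack([x[g].mean(axis=0) for g in groups])
    variances = np.vstack([np.maximum(x[g].var(axis=0), _VAR_FLOOR) for g in groups])
    raw_w = np.array([len(g) / n for g in groups])
    labels = _assign_labels(means[:, 0])

    prune_mass = 0.5  # = n * (1 / (2n)): below half an expected sample
    history = []
    converged = False
    prev_ll = -np.inf
    resp = np.ones((n, len(labels))) / len(labels)
    for _ in range(max_iter):
        pi = _penalized_weights(raw_w, labels, penalty)
        joint = _log_density(x, means, variances) + np.log(pi)
        norm = logsumexp(joint, axis=1)
        ll = float(norm.sum())
        history.append(ll)
        resp = np.exp(joint - norm[:, None])

        nk = resp.sum(axis=0)
        keep = nk >= prune_mass
        if not keep.all():
            if keep.sum() == 0:
                return None
            means, variances, resp = means[keep], variances[keep], resp[:, keep]
            resp = resp / np.maximum(resp.sum(axis=1, keepdims=True), 1e-300)
            nk = resp.sum(axis=0)
            raw_w = nk / n
            labels = _assign_labels(means[:, 0])
            prev_ll = -np.inf  # dimension changed; restart the convergence test
            if len(labels) == 1:
                break
            continue

        raw_w = nk / n
        means = (resp.T @ x) / nk[:, None]
        for j in range(len(labels)):
            d = x - means[j]
            variances[j] = np.maximum(
                (resp[:, j, None] * d * d).sum(axis=0) / nk[j], _VAR_FLOOR
            )
        if prev_ll > -np.inf and abs(ll - prev_ll) <= tol * (abs(prev_ll) + 1e-12):
            converged = True
            break
        prev_ll = ll

    nk = resp.sum(axis=0)
    order = np.argsort(means[:, 0], kind="stable")
    means, variances, nk = means[order], variances[order], nk[order]
    labels = _assign_labels(means[:, 0])
    return {
        "means": means,
        "variances": variances,
        "counts": nk,
        "labels": labels,
        "ll": history[-1],
        "history": history,
        "converged": converged or len(labels) == 1,
    }


def fit_genotype_clusters(
    contrast,
    size,
    inbred_penalty: float = 4.0,
    init_seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> ProbesetModel:
    """Fit genotype components (BB/AB/AA) in (contrast, size) space.

    EM is run for 1, 2 and 3 components (quantile-split initialisation along
    the contrast axis, ties broken by point order) and the fit with the best
    BIC is kept, so a monomorphic probeset resolves to a single cluster and a
    probeset lacking a minor homozygote to two.  The AB prior weight is
    multiplied by ``2**-inbred_penalty`` and renormalised at every E-step.
    Components with posterior mass below 1/(2n) are pruned during fitting.

    Initialisation is deterministic; ``init_seed`` is accepted for interface
    stability but unused.  Missing points (NaN) are ignored.  Requires at
    least 5 informative points.
    """
    c = np.asarray(contrast, dtype=float)
    s = np.asarray(size, dtype=float)
    ok = np.isfinite(c) & np.isfinite(s)
    c, s = c[ok], s[ok]
    n = c.size
    if n < 5:
        raise ValueError(f"need at least 5 informative points, got {n}")

    if np.ptp(c) < _DEGENERATE_SPREAD and np.ptp(s) < _DEGENERATE_SPREAD:
        lab = CALL_AA if c[0] >= 0 else CALL_BB
        return ProbesetModel(
            means=np.array([[c[0], s[0]]]),
            variances=np.full((1, 2), _VAR_FLOOR),
            weights=np.array([1.0]),
            labels=[lab],
            inbred_penalty=inbred_penalty,
            converged=True,
            log_likelihood=0.0,
            n_points=n,
            counts=np.array([float(n)]),
        )

    x = np.column_stack([c, s])
    best = None
    best_bic = np.inf
    for k in (1, 2, 3):
        fit = _fit_k(x, k, inbred_penalty, max_iter, tol)
        if fit is None:
            continue
        kk = len(fit["labels"])
        n_params = 5 * kk - 1  # 2 means + 2 variances per component + k-1 weights
        bic = -2.0 * fit["ll"] + n_params * np.log(n)
        if bic < best_bic - 1e-12:
            best_bic = bic
            best = fit

    pi = _penalized_weights(best["counts"] / n, best["labels"], inbred_penalty)
    return ProbesetModel(
        means=best["means"],
        variances=best["variances"],
        weights=pi,
        labels=best["labels"],
        inbred_penalty=inbred_penalty,
        converged=best["converged"],
        log_likelihood=best["ll"],
        n_points=n,
        counts=best["counts"],
        ll_history=best["history"],
    )


def call_genotypes(
    model: ProbesetModel,
    contrast,
    size,
    confidence_threshold: float = 0.95,
) -> pd.DataFrame:
    """Maximum-posterior genotype calls under a fitted model.

    Returns a DataFrame with columns ``call`` and ``confidence``; points with
    missing coordinates or posterior below the threshold are called NN.
    """
    c = np.atleast_1d(np.asarray(contrast, dtype=float))
    s = np.atleast_1d(np.asarray(size, dtype=float))
    calls = np.full(c.shape, CALL_NN, dtype=object)
    conf = np.zeros(c.shape)
    ok = np.isfinite(c) & np.isfinite(s)
    if ok.any():
        logr = model.log_responsibilities(c[ok], s[ok])
        best = np.argmax(logr, axis=1)
        p = np.exp(logr[np.arange(best.size), best])
        lab = np.array(
            [CALL_OO if model.labels[k] == "OTV" else model.labels[k] for k in best],
            dtype=object,
        )
        lab[p < confidence_threshold] = CALL_NN
        calls[ok] = lab
        conf[ok] = p
    return pd.DataFrame({"call": calls, "confidence": conf})


def detect_otv(
    model: ProbesetModel,
    contrast,
    size,
    otv_size_gap: float = 2.0,
    confidence_threshold: float = 0.95,
    min_carriers: int = 2,
    min_carrier_fraction: float = 0.05,
):
    """Search for a null-allele (OTV) cluster below the genotype clusters.

    Samples whose probe target is deleted hybridise poorly on both channels
    and sit at markedly lower size.  Two detection routes are tried:

    1. *Component route* — if a fitted component's mean size lies at least
       ``otv_size_gap`` pooled size-SDs below every other component's mean
       size, that component is relabelled OTV (the mixture fit often captures
       the null cloud as a component of its own).
    2. *Point route* — otherwise, points lying ``otv_size_gap`` pooled
       size-SDs below the lowest genotype-cluster mean size form a candidate
       subpopulation.  To guard against ordinary lower-tail points the
       candidate set must hold at least ``min_carriers`` points and
       ``min_carrier_fraction`` of the samples, and its mean size must fall
       a further SD below the threshold; it is then fitted as an extra OTV
       component.

    With no such subpopulation the model and calls are returned unchanged.
    If removing the low-size cloud would leave fewer than 2 points the
    probeset is flagged degenerate (no gap can be defined) and not split.

    Returns ``(model, calls)``.
    """
    if model.has_otv:
        return model, call_genotypes(model, contrast, size, confidence_threshold)
    c = np.asarray(contrast, dtype=float)
    s = np.asarray(size, dtype=float)
    ok = np.isfinite(c) & np.isfinite(s)

    # --- component route ---
    if model.n_components >= 2:
        sizes = model.means[:, 1]
        lowest = int(np.argmin(sizes))
        others = [k for k in range(model.n_components) if k != lowest]
        w = np.maximum(model.counts[others], 1.0)
        pooled = float(np.sqrt(np.sum(w * model.variances[others, 1]) / np.sum(w)))
        pooled = max(pooled, np.sqrt(_VAR_FLOOR))
        if sizes[lowest] < np.min(sizes[others]) - otv_size_gap * pooled:
            keep = others
            geno_means = model.means[keep]
            new_labels = _assign_labels(geno_means[:, 0]) + ["OTV"]
            reorder = keep + [lowest]
            new = ProbesetModel(
                means=model.means[reorder],
                variances=model.variances[reorder],
                weights=model.weights[reorder] / model.weights[reorder].sum(),
                labels=new_labels,
                inbred_penalty=model.inbred_penalty,
                converged=model.converged,
                log_likelihood=model.log_likelihood,
                n_points=model.n_points,
                counts=model.counts[reorder],
            )
            return new, call_genotypes(new, c, s, confidence_threshold)

    # --- point route ---
    geno = list(range(model.n_components))
    min_mean_size = float(np.min(model.means[geno, 1]))
    w = np.maximum(model.counts[geno], 1.0)
    pooled = float(np.sqrt(np.sum(w * model.variances[geno, 1]) / np.sum(w)))
    pooled = max(pooled, np.sqrt(_VAR_FLOOR))

    cut = min_mean_size - otv_size_gap * pooled
    low = ok & (s < cut)
    n_low = int(low.sum())
    n_ok = int(ok.sum())
    needed = max(min_carriers, int(np.ceil(min_carrier_fraction * n_ok)))
    if n_low < needed:
        return model, call_genotypes(model, c, s, confidence_threshold)
    if (n_ok - n_low) < 2:
        flagged = replace(model, degenerate=True)
        return flagged, call_genotypes(flagged, c, s, confidence_threshold)
    if float(np.mean(s[low])) >= cut - pooled:
        # lower-tail stragglers, not a separated cloud
        return model, call_genotypes(model, c, s, confidence_threshold)

    xo = np.column_stack([c[low], s[low]])
    frac = n_low / n_ok
    new = ProbesetModel(
        means=np.vstack([model.means, xo.mean(axis=0)]),
        variances=np.vstack([model.variances, np.maximum(xo.var(axis=0), _VAR_FLOOR)]),
        weights=np.append(model.weights * (1.0 - frac), frac),
        labels=list(model.labels) + ["OTV"],
        inbred_penalty=model.inbred_penalty,
        converged=model.converged,
        log_likelihood=model.log_likelihood,
        n_points=model.n_points,
        counts=np.append(model.counts * (1.0 - frac), float(n_low)),
    )
    return new, call_genotypes(new, c, s, confidence_threshold)


def _process_probeset(c, s, penalty, params):
    from polyarray import qc as _qc

    model = fit_genotype_clusters(c, s, inbred_penalty=penalty)
    model, calls = detect_otv(
        model,
        c,
        s,
        otv_size_gap=params.get("otv_size_gap", 2.0),
        confidence_threshold=params.get("confidence_threshold", 0.95),
    )
    metrics = _qc.compute_metrics(calls["call"].to_numpy())
    thresholds = params.get("thresholds") or _qc.QcThresholds()
    category = _qc.classify_probeset(metrics, model, thresholds)
    return model, calls, metrics, category


def two_step_genotyping(signal_table: pd.DataFrame, params: dict | None = None):
    """Two-pass genotype calling over a long-format signal table.

    Pass 1 fits every probeset with a mild inbred penalty (default 4) and
    classifies it; probesets that fail QC as ``Other`` or ``NMH`` are
    refitted with a strong penalty (default 16) and re-classified.  OTV
    detection runs in both passes.  Calls of probesets not reprocessed are
    exactly the pass-1 calls.

    Parameters
    ----------
    signal_table : DataFrame
        Columns ``probeset_id, sample_id, signal_a, signal_b``.
    params : dict, optional
        Keys ``penalty_step1`` (4), ``penalty_step2`` (16),
        ``confidence_threshold``, ``otv_size_gap``, ``thresholds``.

    Returns
    -------
    calls : DataFrame with columns probeset_id, sample_id, call, confidence
    results : dict probeset_id -> dict(model, metrics, category)
    step_log : DataFrame recording reprocessed probesets and both categories
    """
    params = dict(params or {})
    p1 = params.get("penalty_step1", 4.0)
    p2 = params.get("penalty_step2", 16.0)
    required = {"probeset_id", "sample_id", "signal_a", "signal_b"}
    missing_cols = required - set(signal_table.columns)
    if missing_cols:
        raise ValueError(f"signal table lacks columns: {sorted(missing_cols)}")

    all_calls = []
    results: dict = {}
    log_rows = []
    for pid, grp in signal_table.groupby("probeset_id", sort=True):
        c, s = to_contrast_size(grp["signal_a"].to_numpy(), grp["signal_b"].to_numpy())
        model, calls, metrics, category = _process_probeset(c, s, p1, params)
        step1_cat = category.category
        reprocessed = False
        if step1_cat in ("Other", "NMH"):
            model, calls, metrics, category = _process_probeset(c, s, p2, params)
            reprocessed = True
        log_rows.append(
            {
                "probeset_id": pid,
                "reprocessed": reprocessed,
                "category_step1": step1_cat,
                "category_final": category.category,
            }
        )
        results[pid] = {"model": model, "metrics": metrics, "category": category}
        out = calls.copy()
        out.insert(0, "sample_id", grp["sample_id"].to_numpy())
        out.insert(0, "probeset_id", pid)
        all_calls.append(out)

    calls_df = (
        pd.concat(all_calls, ignore_index=True)
        if all_calls
        else pd.DataFrame(columns=["probeset_id", "sample_id", "call", "confidence"])
    )
    step_log = pd.DataFrame(
        log_rows,
        columns=["probeset_id", "reprocessed", "category_step1", "category_final"],
    )
    return calls_df, results, step_log


def calls_to_matrix(calls_df: pd.DataFrame) -> pd.DataFrame:
    """Pivot long-format calls into a samples x loci genotype matrix."""
    if calls_df.empty:
        return pd.DataFrame()
    return calls_df.pivot(index="sample_id", columns="probeset_id", values="call")
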