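"""Second-order linear-chain CRF over BIO labels.

The current label is conditioned on the previous two labels. The model is
realized on an expanded lattice whose states are label pairs (y_{t-1}, y_t):
transition potentials are triples (y_{t-2}, y_{t-1}, y_t) and observation
potentials tie each (binary, string-keyed) feature to the current label.
Two distinguished BOS sentinels pad the left context.

Training maximizes the penalized conditional log-likelihood

    sum_i log P(y_i | x_i) - ||w||^2 / (2 sigma^2)

with the exact gradient (empirical minus expected feature counts, the
latter from forward-backward on the pair lattice) under L-BFGS. All chart
arithmetic is in log space.

Decoding is Viterbi over the same lattice; by default, BIO-illegal
transitions (I-X not preceded by B-X/I-X) are structurally forbidden with
-inf potentials at decode time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.optimize
import scipy.sparse as sp
from scipy.special import logsumexp

from .features import FeatureVector

__all__ = [
    "CRFModel",
    "LabeledSequence",
    "score",
    "make_objective",
    "train",
    "viterbi",
    "marginals",
    "log_partition",
    "save_model",
    "load_model",
]

NEG_INF = -np.inf


def _check_bio_legal(labels: list[str]) -> None:
    prev = "O"
    for lab in labels:
        if lab.startswith("I-"):
            t = lab[2:]
            if not (prev == "B-" + t or prev == "I-" + t):
                raise ValueError(f"illegal BIO sequence: {lab} after {prev}")
        prev = lab


@dataclass
class LabeledSequence:
    """Feature vectors plus a legal BIO label sequence of equal length."""

    feature_vectors: list[FeatureVector]
    labels: list[str]

    def __post_init__(self) -> None:
        if len(self.feature_vectors) != len(self.labels):
            raise ValueError(
                f"{len(self.feature_vectors)} feature vectors vs "
                f"{len(self.labels)} labels"
            )
        _check_bio_legal(self.labels)


@dataclass
class CRFModel:
    labels: list[str]
    feature_index: dict[str, int]
    w_emit: np.ndarray  # (n_features, n_labels)
    w_trans: np.ndarray  # (n_labels+1, n_labels+1, n_labels); index -1 = BOS
    sigma: float = 1.0
    training_log: list[float] = field(default_factory=list)

    @property
    def n_labels(self) -> int:
        return len(self.labels)

    @property
    def bos(self) -> int:
        return len(self.labels)

    def label_id(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise ValueError(f"unknown label {label!r}") from None

    def encode(self, fvs: list[FeatureVector]) -> list[np.ndarray]:
        """Feature-key sets -> index arrays; unknown keys are dropped."""
        out = []
        for fv in fvs:
            idx = [self.feature_index[k] for k in fv.features if k in self.feature_index]
            out.append(np.array(sorted(idx), dtype=np.int64))
        return out

    def emissions(self, fvs: list[FeatureVector]) -> np.ndarray:
        E = np.zeros((len(fvs), self.n_labels))
        for t, ks in enumerate(self.encode(fvs)):
            if len(ks):
                E[t] = self.w_emit[ks].sum(axis=0)
        return E

    def bio_mask(self) -> np.ndarray:
        """(n_labels+1, n_labels) additive mask: -inf where label c may not
        follow label b (I-X requires B-X/I-X of the same type)."""
        L = self.n_labels
        mask = np.zeros((L + 1, L))
        for c, lab in enumerate(self.labels):
            if not lab.startswith("I-"):
                continue
            t = lab[2:]
            for b in range(L + 1):
                prev = self.labels[b] if b < L else "<BOS>"
                if prev not in ("B-" + t, "I-" + t):
                    mask[b, c] = NEG_INF
        return mask


def score(model: CRFModel, fvs: list[FeatureVector], labels: list[str]) -> float:
    """Unnormalized log score: sum_t w.f(x, t, y_{t-2}, y_{t-1}, y_t)."""
    if len(fvs) != len(labels):
        raise ValueError("length mismatch between features and labels")
    y = [model.label_id(lab) for lab in labels]
    E = model.emissions(fvs)
    B = model.bos
    s = 0.0
    for t, c in enumerate(y):
        a = y[t - 2] if t >= 2 else B
        b = y[t - 1] if t >= 1 else B
        s += model.w_trans[a, b, c] + E[t, c]
    return float(s)


def _forward(E: np.ndarray, trans: np.ndarray, B: int):
    """Alpha charts on the pair lattice. Returns (a0, alphas, logZ) where
    alphas[t] (t>=1) is the (L, L) chart over states (y_{t-1}, y_t)."""
    T, L = E.shape
    a0 = trans[B, B, :] + E[0]
    if T == 1:
        return a0, [], float(logsumexp(a0))
    alphas = [a0[:, None] + trans[B, :L, :] + E[1][None, :]]
    for t in range(2, T):
        prev = alphas[-1]  # (a, b)
        m = prev[:, :, None] + trans[:L, :L, :]  # (a, b, c)
        alphas.append(logsumexp(m, axis=0) + E[t][None, :])
    return a0, alphas, float(logsumexp(alphas[-1]))


def _backward(E: np.ndarray, trans: np.ndarray, B: int):
    """Beta charts: betas[t] (t>=1) over states (y_{t-1}, y_t); b0 over the
    virtual t=0 states (BOS, y_0)."""
    T, L = E.shape
    if T == 1:
        return np.zeros(L), []
    betas = [np.zeros((L, L))]  # t = T-1
    for t in range(T - 2, 0, -1):
        nxt = betas[0]  # (b, c)
        m = trans[:L, :L, :] + E[t + 1][None, None, :] + nxt[None, :, :]
        betas.insert(0, logsumexp(m, axis=2))
    b1 = betas[0]  # (y_0, y_1) chart
    b0 = logsumexp(trans[B, :L, :] + E[1][None, :] + b1, axis=1)
    return b0, betas


def log_partition(model: CRFModel, fvs: list[FeatureVector]) -> float:
    if not fvs:
        return 0.0
    E = model.emissions(fvs)
    _a0, _alphas, logZ = _forward(E, model.w_trans, model.bos)
    return logZ


def marginals(
    model: CRFModel, fvs: list[FeatureVector], constrain_bio: bool = False
) -> np.ndarray:
    """Per-position label posteriors P(y_t = c | x), shape (T, n_labels)."""
    T = len(fvs)
    L = model.n_labels
    if T == 0:
        return np.zeros((0, L))
    E = model.emissions(fvs)
    trans = model.w_trans
    if constrain_bio:
        trans = model.w_trans + model.bio_mask()[np.newaxis, :, :]
    a0, alphas, logZ = _forward(E, trans, model.bos)
    b0, betas = _backward(E, trans, model.bos)
    P = np.zeros((T, L))
    P[0] = np.exp(a0 + b0 - logZ)
    for t in range(1, T):
        pair = alphas[t - 1] + betas[t - 1] - logZ
        P[t] = np.exp(logsumexp(pair, axis=0))
    return P


def viterbi(
    model: CRFModel, fvs: list[FeatureVector], constrain_bio: bool = True
) -> tuple[list[str], float]:
    """Most probable label sequence and its log-probability.

    Ties are broken toward the earlier label in the alphabet. With
    ``constrain_bio`` (default), BIO-illegal transitions get -inf potential.
    """
    T = len(fvs)
    L = model.n_labels
    B = model.bos
    if T == 0:
        return [], 0.0
    E = model.emissions(fvs)
    trans = model.w_trans
    if constrain_bio:
        trans = model.w_trans + model.bio_mask()[np.newaxis, :, :]
    a0 = trans[B, B, :] + E[0]
    if T == 1:
        c = int(np.argmax(a0))
        return [model.labels[c]], float(a0[c] - logsumexp(a0))
    _a0f, _alphas, logZ = _forward(E, trans, B)
    delta = a0[:, None] + trans[B, :L, :] + E[1][None, :]  # (y0, y1)
    backptr = []
    for t in range(2, T):
        m = delta[:, :, None] + trans[:L, :L, :]  # (a, b, c)
        backptr.append(m.argmax(axis=0))  # (b, c) -> best a
        delta = m.max(axis=0) + E[t][None, :]
    b, c = np.unravel_index(int(np.argmax(delta)), delta.shape)
    best = float(delta[b, c])
    ys = [int(b), int(c)]
    for bp in reversed(backptr):
        a = int(bp[ys[0], ys[1]])
        ys.insert(0, a)
    return [model.labels[y] for y in ys], best - logZ


def _empirical_counts(model_shape, data_enc, n_features, L, B):
    emp_emit = np.zeros((n_features, L))
    emp_trans = np.zeros((L + 1, L + 1, L))
    for ks_list, y in data_enc:
        for t, c in enumerate(y):
            a = y[t - 2] if t >= 2 else B
            b = y[t - 1] if t >= 1 else B
            emp_trans[a, b, c] += 1.0
            emp_emit[ks_list[t], c] += 1.0
    return emp_emit, emp_trans


def make_objective(
    data: list[LabeledSequence],
    sigma: float = 1.0,
    labels: list[str] | None = None,
):
    """Negative penalized log-likelihood and its exact gradient.

    Returns ``(objective, labels, feature_index)`` where
    ``objective(w) -> (value, gradient)`` over the flat parameter vector
    (emission weights followed by transition weights). Exposed separately
    from :func:`train` so the analytic gradient can be checked against
    finite differences.
    """
    if not data:
        raise ValueError("no training sequences")
    if labels is None:
        seen = {lab for seq in data for lab in seq.labels}
        labels = (["O"] if "O" in seen else []) + sorted(seen - {"O"})
    L = len(labels)
    lab_id = {lab: i for i, lab in enumerate(labels)}
    B = L

    feature_index: dict[str, int] = {}
    for seq in data:
        for fv in seq.feature_vectors:
            for k in sorted(fv.features):
                if k not in feature_index:
                    feature_index[k] = len(feature_index)
    F = len(feature_index)

    # one big CSR over all positions of all sequences
    indptr = [0]
    indices: list[int] = []
    seq_bounds = []
    data_enc = []
    pos = 0
    for seq in data:
        ks_list = []
        for fv in seq.feature_vectors:
            ks = sorted(feature_index[k] for k in fv.features)
            indices.extend(ks)
            indptr.append(len(indices))
            ks_list.append(np.array(ks, dtype=np.int64))
        y = [lab_id[lab] for lab in seq.labels]
        data_enc.append((ks_list, y))
        seq_bounds.append((pos, pos + len(y)))
        pos += len(y)
    N = pos
    X = sp.csr_matrix(
        (np.ones(len(indices)), np.array(indices, dtype=np.int64), np.array(indptr)),
        shape=(N, F),
    )
    emp_emit, emp_trans = _empirical_counts(None, data_enc, F, L, B)

    n_emit = F * L
    n_trans = (L + 1) * (L + 1) * L

    def unpack(w):
        return w[:n_emit].reshape(F, L), w[n_emit:].reshape(L + 1, L + 1, L)

    def objective(w):
        w_emit, w_trans = unpack(w)
        E_all = np.asarray(X @ w_emit)
        ll = 0.0
        P_all = np.zeros((N, L))
        exp_trans = np.zeros((L + 1, L + 1, L))
        for si, ((ks_list, y), (lo, hi)) in enumerate(zip(data_enc, seq_bounds)):
            E = E_all[lo:hi]
            T = hi - lo
            # gold score
            s = 0.0
            for t, c in enumerate(y):
                a = y[t - 2] if t >= 2 else B
                b = y[t - 1] if t >= 1 else B
                s += w_trans[a, b, c] + E[t, c]
            a0, alphas, logZ = _forward(E, w_trans, B)
            if not np.isfinite(logZ):
                raise FloatingPointError(
                    f"non-finite partition function on sequence {si}"
                )
            ll += s - logZ
            b0, betas = _backward(E, w_trans, B)
            P_all[lo] = np.exp(a0 + b0 - logZ)
            exp_trans[B, B, :] += P_all[lo]
            if T >= 2:
                pair1 = np.exp(alphas[0] + betas[0] - logZ)
                exp_trans[B, :L, :] += pair1
                P_all[lo + 1] = pair1.sum(axis=0)
            for t in range(2, T):
                trip = np.exp(
                    alphas[t - 2][:, :, None]
                    + w_trans[:L, :L, :]
                    + E[t][None, None, :]
                    + betas[t - 1][None, :, :]
                    - logZ
                )
                exp_trans[:L, :L, :] += trip
                P_all[lo + t] = trip.sum(axis=(0, 1))
        exp_emit = np.asarray(X.T @ P_all)
        penalty = (w @ w) / (2.0 * sigma**2)
        g_emit = -(emp_emit - exp_emit)
        g_trans = -(emp_trans - exp_trans)
        grad = np.concatenate([g_emit.ravel(), g_trans.ravel()]) + w / sigma**2
        return -(ll) + penalty, grad

    return objective, labels, feature_index


def train(
    data: list[LabeledSequence],
    sigma: float = 1.0,
    tolerance: float = 1e-5,
    max_iter: int = 200,
    labels: list[str] | None = None,
) -> CRFModel:
    """Penalized maximum-likelihood training by L-BFGS on the exact gradient.

    ``labels`` fixes the label alphabet order; by default it is O first,
    then the remaining labels sorted. ``training_log`` on the returned model
    holds the (monotone non-increasing) objective at each accepted step.
    """
    objective, labels, feature_index = make_objective(data, sigma, labels)
    L = len(labels)
    F = len(feature_index)
    n_emit = F * L

    w0 = np.zeros(n_emit + (L + 1) * (L + 1) * L)
    log: list[float] = []

    # cache last objective value for the accepted-step trace
    objective_cache_last = [np.inf]

    def cb(wk):
        log.append(float(objective_cache_last[0]))

    def wrapped(w):
        f, g = objective(w)
        objective_cache_last[0] = f
        return f, g

    res = scipy.optimize.minimize(
        wrapped,
        w0,
        jac=True,
        method="L-BFGS-B",
        callback=cb,
        options={"maxiter": max_iter, "ftol": tolerance, "gtol": 1e-8},
    )
    w_emit = res.x[:n_emit].reshape(F, L)
    w_trans = res.x[n_emit:].reshape(L + 1, L + 1, L)
    return CRFModel(
        labels=labels,
        feature_index=feature_index,
        w_emit=np.asarray(w_emit),
        w_trans=np.asarray(w_trans),
        sigma=sigma,
        training_log=log,
    )


def save_model(model: CRFModel, path) -> None:
    """Versioned flat text serialization; load(save(m)) reproduces m."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("chemner-crf\t1\n")
        fh.write("labels\t" + "\t".join(model.labels) + "\n")
        fh.write(f"sigma\t{model.sigma!r}\n")
        for key, idx in model.feature_index.items():
            vals = " ".join(repr(float(v)) for v in model.w_emit[idx])
            fh.write(f"F\t{key}\t{vals}\n")
        L = model.n_labels
        for a in range(L + 1):
            for b in range(L + 1):
                vals = " ".join(repr(float(v)) for v in model.w_trans[a, b])
                fh.write(f"T\t{a}\t{b}\t{vals}\n")


def load_model(path) -> CRFModel:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:1] != ["chemner-crf"]:
            raise ValueError("not a chemner CRF model file")
        labels = fh.readline().rstrip("\n").split("\t")[1:]
        sigma = float(fh.readline().rstrip("\n").split("\t")[1])
        L = len(labels)
        feature_index: dict[str, int] = {}
        emit_rows: list[list[float]] = []
        w_trans = np.zeros((L + 1, L + 1, L))
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "F":
                feature_index[parts[1]] = len(feature_index)
                emit_rows.append([float(x) for x in parts[2].split(" ")])
            elif parts[0] == "T":
                a, b = int(parts[1]), int(parts[2])
                w_trans[a, b] = [float(x) for x in parts[3].split(" ")]
    w_emit = np.array(emit_rows) if emit_rows else np.zeros((0, L))
    return CRFModel(
        labels=labels,
        feature_index=feature_index,
        w_emit=w_emit,
        w_trans=w_trans,
        sigma=sigma,
    )
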