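"""Sentence-embedding training objectives over cosine similarities.

Three objectives from the contrastive sentence-embedding literature:

* CoSENT — a pairwise ranking loss directly on cosine similarities,
  ``log(1 + sum_{pos, neg} exp(lambda * (cos_neg - cos_pos)))``, summed over
  every (positive-pair, negative-pair) cross combination in the batch. It
  aligns the training objective with cosine-based retrieval at inference,
  which is why it is the default here.
* supervised SimCSE — a temperature-scaled InfoNCE over anchor/positive/
  hard-negative triads.
* SBERT softmax — classification over ``concat(u, v, |u - v|)``; train-time
  only, inference always falls back to cosine.

Each function accepts either plain arrays (returning floats) or autodiff
:class:`~prser.autodiff.Tensor` inputs (returning a Tensor on the tape).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .autodiff import Tensor, concatenate, logsumexp, stack

DEFAULT_COSENT_SCALE = 20.0  # published CoSENT default
DEFAULT_SIMCSE_TAU = 0.05    # published SimCSE default


def _as_tensor(x) -> tuple[Tensor, bool]:
    if isinstance(x, Tensor):
        return x, True
    return Tensor(np.asarray(x, dtype=np.float64)), False


def cosine(u, v) -> float | Tensor:
    """Cosine similarity ``u.v / (|u||v|)``; errors on zero-norm input."""
    ut, u_live = _as_tensor(u)
    vt, v_live = _as_tensor(v)
    nu = (ut * ut).sum() ** 0.5
    nv = (vt * vt).sum() ** 0.5
    if float(nu.data) == 0.0 or float(nv.data) == 0.0:
        raise ValueError("cosine undefined for zero-norm vectors")
    out = (ut * vt).sum() / (nu * nv)
    return out if (u_live or v_live) else float(out.data)


def pairwise_cosine(A, B) -> Tensor | np.ndarray:
    """Row-wise cosine between aligned matrices A and B (n, d) -> (n,)."""
    At, a_live = _as_tensor(A)
    Bt, b_live = _as_tensor(B)
    na = ((At * At).sum(axis=-1)) ** 0.5
    nb = ((Bt * Bt).sum(axis=-1)) ** 0.5
    out = (At * Bt).sum(axis=-1) / (na * nb)
    return out if (a_live or b_live) else out.data


def cosent_loss(cosines, labels, scale: float = DEFAULT_COSENT_SCALE) -> float | Tensor:
    """CoSENT ranking loss over a batch of labeled pair cosines.

    ``labels`` are 1 for same-prescription pairs, 0 otherwise. The sum runs
    over all (positive, negative) cross combinations; with no positives or
    no negatives the empty sum gives ``log(1) = 0``. Computed via a
    numerically stable log-sum-exp with an implicit 0 term.
    """
    if scale <= 0:
        raise ValueError("CoSENT scale must be positive")
    ct, live = _as_tensor(cosines)
    lab = np.asarray(labels)
    if ct.data.shape != lab.shape:
        raise ValueError("cosines and labels must have equal length")
    pos_idx = np.flatnonzero(lab == 1)
    neg_idx = np.flatnonzero(lab == 0)
    if len(pos_idx) == 0 or len(neg_idx) == 0:
        zero = Tensor(0.0)
        return zero if live else 0.0
    pos = ct[pos_idx]
    neg = ct[neg_idx]
    # terms lambda*(cos_neg - cos_pos) for every cross pair, plus the
    # implicit exp(0) of the "1 +" term
    diff = (neg.reshape(1, -1) - pos.reshape(-1, 1)) * scale
    flat = concatenate([Tensor(np.zeros(1)), diff.reshape(-1)], axis=0)
    out = logsumexp(flat)
    return out if live else float(out.data)


def simcse_sup_loss(anchor, positive, negatives_pos: Sequence, negatives_hard: Sequence,
                    tau: float = DEFAULT_SIMCSE_TAU) -> float | Tensor:
    """Supervised SimCSE loss for one anchor.

    ``negatives_pos`` are the other in-batch positives (h_j^+, including
    this anchor's own positive) and ``negatives_hard`` the hard negatives
    (h_j^-). The loss is ``-log`` of the anchor-positive term over the sum
    of all denominator terms at temperature ``tau``.
    """
    if tau <= 0:
        raise ValueError("temperature must be positive")
    at, live = _as_tensor(anchor)
    pt, p_live = _as_tensor(positive)
    live = live or p_live
    denom_terms: list[Tensor] = []
    for other in list(negatives_pos) + list(negatives_hard):
        ot, o_live = _as_tensor(other)
        live = live or o_live
        denom_terms.append(cosine(at, ot))  # Tensor inputs -> Tensor output
    if not denom_terms:
        raise ValueError("empty SimCSE denominator")
    num = cosine(at, pt)
    scaled = stack([t * (1.0 / tau) for t in denom_terms], axis=0).reshape(-1)
    out = logsumexp(scaled) - num * (1.0 / tau)
    return out if live else float(out.data)


def simcse_sup_batch(anchors, positives, hard_negatives,
                     tau: float = DEFAULT_SIMCSE_TAU) -> float:
    """Mean supervised-SimCSE loss over a batch of aligned triads."""
    n = len(anchors)
    losses = [
        simcse_sup_loss(anchors[i], positives[i],
                        list(positives), list(hard_negatives), tau)
        for i in range(n)
    ]
    vals = [float(l.data) if isinstance(l, Tensor) else l for l in losses]
    return float(np.mean(vals))


def sbert_objective(u, v, weight, label: int | np.ndarray):
    """SBERT classification objective on ``concat(u, v, |u - v|)``.

    ``weight`` has shape (3n, k). Returns ``(probabilities, cross_entropy)``;
    with batched inputs (B, n) the cross-entropy is the batch mean.
    """
    ut, u_live = _as_tensor(u)
    vt, v_live = _as_tensor(v)
    wt, w_live = _as_tensor(weight)
    live = u_live or v_live or w_live
    if ut.data.shape != vt.data.shape:
        raise ValueError("u and v must have identical shapes")
    n = ut.data.shape[-1]
    if wt.data.shape[0] != 3 * n:
        raise ValueError(f"weight must have 3*{n} rows, got {wt.data.shape[0]}")
    feats = concatenate([ut, vt, (ut - vt).abs()], axis=-1)
    logits = feats @ wt
    shift = Tensor(logits.data.max(axis=-1, keepdims=True))
    e = (logits - shift).exp()
    probs = e / e.sum(axis=-1, keepdims=True)
    lse = logsumexp(logits, axis=-1)
    lab = np.asarray(label)
    if logits.data.ndim == 1:
        picked = logits[int(lab)]
        ce = lse - picked
    else:
        rows = np.arange(logits.data.shape[0])
        picked = logits[rows, lab]
        ce = (lse - picked).mean()
    if live:
        return probs, ce
    return probs.data, float(ce.data)
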