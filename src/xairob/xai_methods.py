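"""Eight per-token attribution methods for instrumented transformers.

Six are transformer-specific — raw attention maps, attention rollout, and
the class-activated-gradient family (Grads, AttGrads, CAT, AttCAT) — one
is gradient-based (integrated gradients on the embedding path) and one is
perturbation-based (Shapley values with a PAD-token baseline).  Every
method emits a vector with one entry per full-string token position
(including BOS/EOS/PAD); scores with an extra embedding or key axis are
averaged over that axis so methods are comparable.  Normalisation divides
by the absolute sum over the full string.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .autograd import Tensor, no_grad
from .chem_data import TokenSequence
from .transformer_models import (
    AttentionTrace,
    GradientTrace,
    ToxicityClassifier,
)

METHODS = (
    "AttentionMaps",
    "Rollout",
    "Grads",
    "AttGrads",
    "CAT",
    "AttCAT",
    "IG",
    "SHAP",
)


@dataclass
class Attribution:
    """Per-token importance vector for one method/model/input/class."""

    method: str
    values: np.ndarray  # (S,), full padded string length
    class_index: int | None = None
    normalized: bool = False
    zero_flag: bool = False  # normalisation saw an all-zero vector
    extra: dict | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError(f"{self.method}: non-finite attribution values")


def reduce_embedding(raw: np.ndarray) -> np.ndarray:
    """Average a (S, n) score matrix over its second axis; (S,) passes through."""
    raw = np.asarray(raw, dtype=float)
    if raw.ndim == 1:
        return raw
    if raw.ndim != 2 or raw.shape[1] == 0:
        raise ValueError(f"expected (S, n) scores, got shape {raw.shape}")
    return raw.mean(axis=1)


def normalize_attribution(att: Attribution) -> Attribution:
    """phi_hat_i = phi_i / sum_k |phi_k| over the full token string."""
    total = np.abs(att.values).sum()
    if total == 0:
        return Attribution(
            method=att.method, values=att.values.copy(),
            class_index=att.class_index, normalized=True, zero_flag=True,
            extra=att.extra,
        )
    return Attribution(
        method=att.method, values=att.values / total,
        class_index=att.class_index, normalized=True, extra=att.extra,
    )


# ---------------------------------------------------------------------------
# attention-based methods


def reduce_attention(mat: np.ndarray) -> np.ndarray:
    """Average an (S, S) attention-shaped score over the query axis.

    phi_j is the mean score token j receives across all query positions.
    Averaging over the key axis instead would collapse any row-stochastic
    matrix to the constant 1/S and carry no information.
    """
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"expected a square score matrix, got {mat.shape}")
    return mat.mean(axis=0)


def attention_map_attribution(trace: AttentionTrace) -> Attribution:
    """Raw last-layer attention, head-averaged, averaged over queries."""
    alpha = trace.alpha[-1].mean(axis=0)  # (S, S)
    return Attribution(method="AttentionMaps", values=reduce_attention(alpha))


def rollout_attribution(trace: AttentionTrace, literal: bool = False) -> Attribution:
    """Attention rollout: per-layer head-averaged attention multiplied
    through the layers.

    Default convention mixes in the residual path — 0.5(alpha + I) with row
    renormalisation — before multiplying; `literal=True` multiplies the raw
    head-averaged attention matrices only (in which case a single-layer
    rollout coincides with the raw attention map)."""
    S = trace.alpha.shape[-1]
    joint = np.eye(S)
    for layer in range(trace.layers):
        a = trace.alpha[layer].mean(axis=0)
        if not literal:
            a = 0.5 * (a + np.eye(S))
            a = a / a.sum(axis=-1, keepdims=True)
        joint = a @ joint
    return Attribution(method="Rollout", values=reduce_attention(joint))


def grad_attribution(trace: AttentionTrace, grads: GradientTrace) -> Attribution:
    """Class gradient w.r.t. last-layer attention, head-averaged, row-reduced."""
    _check_shapes(trace, grads)
    g = grads.d_alpha[-1].mean(axis=0)
    return Attribution(
        method="Grads", values=reduce_attention(g), class_index=grads.class_index
    )


def attgrad_attribution(trace: AttentionTrace, grads: GradientTrace) -> Attribution:
    """Sum over layers of (head-averaged gradient) ⊙ (head-averaged attention)."""
    _check_shapes(trace, grads)
    S = trace.alpha.shape[-1]
    acc = np.zeros((S, S))
    for layer in range(trace.layers):
        acc += grads.d_alpha[layer].mean(axis=0) * trace.alpha[layer].mean(axis=0)
    return Attribution(
        method="AttGrads", values=reduce_attention(acc), class_index=grads.class_index
    )


def cat_attribution(trace: AttentionTrace, grads: GradientTrace) -> Attribution:
    """Sum over layers of (gradient w.r.t. h_out) ⊙ h_out, embedding-averaged."""
    _check_shapes(trace, grads)
    acc = (grads.d_hout * trace.h_out).sum(axis=0)  # (S, E)
    return Attribution(
        method="CAT", values=reduce_embedding(acc), class_index=grads.class_index
    )


def attcat_attribution(trace: AttentionTrace, grads: GradientTrace) -> Attribution:
    """CAT weighted by attention: each token's gradient ⊙ output term is
    scaled by the mean attention the token receives (head-averaged, query-
    averaged) before the layer sum and embedding average."""
    _check_shapes(trace, grads)
    S, E = trace.h_out.shape[1:]
    acc = np.zeros((S, E))
    for layer in range(trace.layers):
        a_tok = trace.alpha[layer].mean(axis=0).mean(axis=0)  # (S,) received
        acc += a_tok[:, None] * grads.d_hout[layer] * trace.h_out[layer]
    return Attribution(
        method="AttCAT", values=reduce_embedding(acc), class_index=grads.class_index
    )


def _check_shapes(trace: AttentionTrace, grads: GradientTrace) -> None:
    if trace.alpha.shape != grads.d_alpha.shape or trace.h_out.shape != grads.d_hout.shape:
        raise ValueError(
            f"trace/gradient shape mismatch: {trace.alpha.shape} vs "
            f"{grads.d_alpha.shape}, {trace.h_out.shape} vs {grads.d_hout.shape}"
        )


# ---------------------------------------------------------------------------
# integrated gradients


def integrated_gradients(
    model: ToxicityClassifier,
    seq: TokenSequence,
    class_index: int,
    steps: int = 64,
    baseline_ids: np.ndarray | None = None,
    completeness_tol: float = 0.05,
) -> Attribution:
    """Integrated gradients on the embedding path from an all-PAD baseline.

    The input representation (token embedding + positional encoding) is
    interpolated from the baseline's to the input's in `steps` midpoint
    Riemann samples; per-dimension scores (x - x̄) ⊙ mean-gradient are
    averaged over the embedding axis.  The completeness gap
    |Σφ − (f(x) − f(x̄))| is reported in `extra` and a warning flag set if
    it exceeds `completeness_tol` relative to |f(x) − f(x̄)|.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    ids = np.asarray(seq.ids, dtype=np.intp)
    if baseline_ids is None:
        baseline_ids = np.full_like(ids, seq.vocab.pad_id)
    if baseline_ids.shape != ids.shape:
        raise ValueError("baseline length must match input length")
    key_mask = ids != seq.vocab.pad_id
    with no_grad():
        x = model.encoder.embed(ids).data[0]
        x_bar = model.encoder.embed(baseline_ids).data[0]
    diff = x - x_bar
    S, E = x.shape
    chunk = max(1, int(2e5 / max(S * E, 1)))

    def path_gradients(ts: np.ndarray) -> np.ndarray:
        """Gradient of the class logit at each path point (len(ts), S, E)."""
        grads = []
        for sel in np.array_split(ts, max(1, int(np.ceil(len(ts) / chunk)))):
            points = x_bar[None] + sel[:, None, None] * diff[None]
            inputs = Tensor(points, requires_grad=True)
            logits, _, _, _ = model.forward_tensors(
                inputs=inputs, key_mask=np.repeat(key_mask[None], len(sel), axis=0)
            )
            logits[:, class_index].sum().backward()
            grads.append(inputs.grad)
        return np.concatenate(grads, axis=0)

    def path_values(ts: np.ndarray) -> np.ndarray:
        """Class logit at each path point (forward only)."""
        vals = []
        for sel in np.array_split(ts, max(1, int(np.ceil(len(ts) / (4 * chunk))))):
            points = x_bar[None] + sel[:, None, None] * diff[None]
            with no_grad():
                logits, _, _, _ = model.forward_tensors(
                    inputs=Tensor(points),
                    key_mask=np.repeat(key_mask[None], len(sel), axis=0),
                )
            vals.append(logits.data[:, class_index])
        return np.concatenate(vals)

    def integrate(lo: float, hi: float, n: int, refine: bool) -> np.ndarray:
        """Per-dimension path integral over [lo, hi] with n midpoint cells.

        Each cell's per-dimension contribution is rescaled so its total
        matches the exact mass f(b) - f(a) from boundary evaluations (the
        completeness control variate); cells where the midpoint direction
        disagrees too strongly with the exact mass — an activation-pattern
        switch inside the cell — are subdivided once instead.
        """
        width = (hi - lo) / n
        mids = lo + (np.arange(n) + 0.5) * width
        bounds = lo + np.arange(n + 1) * width
        d = path_gradients(mids) * diff[None] * width  # (n, S, E)
        mass = d.sum(axis=(1, 2))
        exact = np.diff(path_values(bounds))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(mass != 0, exact / mass, np.inf)
        stable = (ratio > 0.2) & (ratio < 5.0)
        total = np.zeros_like(diff)
        for k in range(n):
            if stable[k]:
                total += d[k] * ratio[k]
            elif refine and abs(exact[k]) > 1e-12:
                total += integrate(bounds[k], bounds[k + 1], 8, refine=False)
            else:
                total += d[k]
        return total

    scores = integrate(0.0, 1.0, steps, refine=steps >= 8)
    # endpoint values with the same fixed attention mask as the path
    with no_grad():
        ends, _, _, _ = model.forward_tensors(
            inputs=Tensor(np.stack([x, x_bar])),
            key_mask=np.repeat(key_mask[None], 2, axis=0),
        )
    f_x, f_bar = ends.data[0, class_index], ends.data[1, class_index]
    gap = abs(scores.sum() - (f_x - f_bar))
    denom = max(abs(f_x - f_bar), 1e-12)
    return Attribution(
        method="IG",
        values=reduce_embedding(scores),
        class_index=class_index,
        extra={
            "completeness_gap": float(gap),
            "completeness_gap_relative": float(gap / denom),
            "completeness_warning": bool(gap / denom > completeness_tol),
            "steps": steps,
        },
    )


# ---------------------------------------------------------------------------
# Shapley values

EXACT_SHAP_LIMIT = 12


def _shapley_exact(
    n: int, value: Callable[[tuple[int, ...]], float]
) -> np.ndarray:
    """Exact Shapley values of an n-player game by subset enumeration."""
    players = range(n)
    phi = np.zeros(n)
    cache: dict[tuple[int, ...], float] = {}

    def v(coalition: tuple[int, ...]) -> float:
        if coalition not in cache:
            cache[coalition] = value(coalition)
        return cache[coalition]

    for k in players:
        others = [p for p in players if p != k]
        for size in range(n):
            weight = (
                math.factorial(size) * math.factorial(n - size - 1) / math.factorial(n)
            )
            for subset in itertools.combinations(others, size):
                with_k = tuple(sorted(subset + (k,)))
                phi[k] += weight * (v(with_k) - v(subset))
    return phi


def shap_attribution(
    model: ToxicityClassifier,
    seq: TokenSequence,
    class_index: int,
    mode: str = "sampled",
    budget: int = 32,
    seed: int = 0,
) -> Attribution:
    """Shapley token attribution with PAD as the absent-token baseline.

    A token is "present" when it keeps its original id and "absent" when
    replaced by PAD; the payoff is the class logit.  Exact mode enumerates
    all coalitions (only for at most 12 non-special tokens); sampled mode
    averages marginal contributions over `budget` random permutations.
    The efficiency gap |Σφ − (f(x) − f(x̄))| is reported in `extra`.
    """
    ids = np.asarray(seq.ids, dtype=np.intp)
    positions = seq.smiles_positions()
    n = len(positions)
    pad = seq.vocab.pad_id

    def batch_value(coalitions: list[tuple[int, ...]]) -> np.ndarray:
        batch = np.repeat(ids[None], len(coalitions), axis=0)
        for row, coalition in enumerate(coalitions):
            absent = [positions[p] for p in range(n) if p not in coalition]
            batch[row, absent] = pad
        return model.logits(batch)[:, class_index]

    if mode == "exact":
        if n > EXACT_SHAP_LIMIT:
            raise ValueError(
                f"{n} tokens: exact enumeration limited to {EXACT_SHAP_LIMIT}; "
                "use mode='sampled'"
            )
        all_coalitions = [
            tuple(sorted(c))
            for size in range(n + 1)
            for c in itertools.combinations(range(n), size)
        ]
        values = dict(zip(all_coalitions, batch_value(all_coalitions)))
        phi_pos = _shapley_exact(n, lambda c: values[tuple(sorted(c))])
        v_full, v_empty = values[tuple(range(n))], values[()]
    elif mode == "sampled":
        rng = np.random.default_rng(seed)
        phi_pos = np.zeros(n)
        prefixes: list[tuple[int, ...]] = [()]
        orders = [rng.permutation(n) for _ in range(budget)]
        for order in orders:
            for stop in range(1, n + 1):
                prefixes.append(tuple(sorted(order[:stop])))
        vals = batch_value(prefixes)
        v_empty = vals[0]
        idx = 1
        for order in orders:
            prev = v_empty
            for stop in range(1, n + 1):
                phi_pos[order[stop - 1]] += vals[idx] - prev
                prev = vals[idx]
                idx += 1
        phi_pos /= budget
        v_full = batch_value([tuple(range(n))])[0]
    else:
        raise ValueError(f"unknown mode {mode!r}")

    values_full = np.zeros(len(ids))
    values_full[positions] = phi_pos
    gap = abs(phi_pos.sum() - (v_full - v_empty))
    return Attribution(
        method="SHAP",
        values=values_full,
        class_index=class_index,
        extra={"efficiency_gap": float(gap), "mode": mode},
    )


# ---------------------------------------------------------------------------
# dispatch


def compute_attribution(
    method: str,
    model: ToxicityClassifier,
    seq: TokenSequence,
    class_index: int | None = None,
    trace: AttentionTrace | None = None,
    grads: GradientTrace | None = None,
    rollout_literal: bool = False,
    ig_steps: int = 64,
    shap_mode: str = "sampled",
    shap_budget: int = 16,
    seed: int = 0,
) -> Attribution:
    """Run one named method, computing traces/gradients as needed.

    `class_index=None` attributes the predicted class.
    """
    from .transformer_models import class_gradients, forward_with_trace

    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    if trace is None:
        prediction, trace = forward_with_trace(model, seq)
        if class_index is None:
            class_index = prediction["class_index"]
    if class_index is None:
        class_index = int(trace.logits.argmax())
    if method == "AttentionMaps":
        att = attention_map_attribution(trace)
    elif method == "Rollout":
        att = rollout_attribution(trace, literal=rollout_literal)
    elif method in ("Grads", "AttGrads", "CAT", "AttCAT"):
        if grads is None:
            grads = class_gradients(model, seq, class_index)
        fn = {
            "Grads": grad_attribution,
            "AttGrads": attgrad_attribution,
            "CAT": cat_attribution,
            "AttCAT": attcat_attribution,
        }[method]
        att = fn(trace, grads)
    elif method == "IG":
        att = integrated_gradients(model, seq, class_index, steps=ig_steps)
    else:
        att = shap_attribution(
            model, seq, class_index, mode=shap_mode, budget=shap_budget, seed=seed
        )
    att.class_index = class_index
    return att
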