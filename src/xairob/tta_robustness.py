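"""Test-time augmentation robustness of token attributions.

The central idea: one molecule admits many SMILES strings, and a robust
explanation should not depend on which string is shown to the model.  Each
augmentation's attribution is normalised over its full token string, the
atom-token entries are extracted and permuted into the molecule's canonical
atom order, and the aligned vectors are compared by pairwise cosine
distance.  The mean of the pairwise matrix is the robustness score (lower =
more self-consistent).  The same machinery supports in-between-model and
in-between-method comparisons, attribution entropy, and the relative
importance given to structural-alert atoms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cosine as _scipy_cosine

from .chem_data import (
    AlertSet,
    MoleculeRecord,
    TokenSequence,
    canonical_atom_ranks,
    enumerate_smiles,
    match_alerts,
    tokenize,
)
from .xai_methods import Attribution, compute_attribution, normalize_attribution

logger = logging.getLogger(__name__)


@dataclass
class AlignedAtomAttribution:
    """Atom-only attribution in canonical atom order.

    `values[r]` is the normalised attribution of the heavy atom whose
    canonical rank is `r`, so vectors from different SMILES of the same
    molecule are directly comparable entry by entry.  `normalization_base`
    keeps the full-string absolute sum the values were divided by.
    """

    molecule_id: str
    source_smiles: str
    values: np.ndarray
    normalization_base: float = 1.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class RobustnessReport:
    """Aggregated pairwise-distance results for one grouping."""

    scores: dict[str, float] = field(default_factory=dict)  # molecule -> mean dist
    matrices: dict[str, np.ndarray] = field(default_factory=dict)
    distances: pd.DataFrame | None = None
    excluded_zero_vectors: int = 0

    def to_tidy(self) -> pd.DataFrame:
        if self.distances is not None:
            return self.distances
        rows = [
            {"molecule_id": mol, "robustness_score": score}
            for mol, score in self.scores.items()
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# alignment


def align_atom_attributions(
    att: Attribution, seq: TokenSequence, ranks: list[int],
    molecule_id: str = "", source_smiles: str = "",
) -> AlignedAtomAttribution:
    """Extract atom-token values and permute them into canonical atom order.

    `att` must be normalised over the full string of `seq`; `ranks` must
    come from the same source SMILES.  Raises if the tokenizer and the
    structure parser disagree on the heavy-atom count.
    """
    if not att.normalized:
        att = normalize_attribution(att)
    atom_positions = seq.atom_positions()
    if len(atom_positions) != len(ranks):
        raise ValueError(
            f"tokenizer found {len(atom_positions)} atoms but ranks cover "
            f"{len(ranks)}"
        )
    aligned = np.zeros(len(ranks))
    for pos in atom_positions:
        atom_idx = seq.atom_of_token[pos]
        aligned[ranks[atom_idx]] = att.values[pos]
    return AlignedAtomAttribution(
        molecule_id=molecule_id,
        source_smiles=source_smiles,
        values=aligned,
        normalization_base=float(np.abs(att.values).sum()) or 1.0,
    )


def attribute_augmented_multi(
    model,
    methods: list[str],
    molecule: MoleculeRecord,
    n_augment: int = 10,
    seed: int = 0,
    class_index: int | None = None,
    **method_kwargs,
) -> dict[str, list[AlignedAtomAttribution]]:
    """Attribute canonical + `n_augment` randomized SMILES for several methods.

    The attention trace and class gradients of each augmented string are
    computed once and shared across methods.  Returns, per method,
    n_augment + 1 aligned atom attributions (canonical first).
    """
    from .transformer_models import class_gradients, forward_with_trace

    if n_augment < 1:
        raise ValueError("n_augment must be >= 1")
    canonical = molecule.smiles_canonical
    variants = [canonical] + enumerate_smiles(canonical, n_augment, seed)
    out: dict[str, list[AlignedAtomAttribution]] = {m: [] for m in methods}
    grad_methods = {"Grads", "AttGrads", "CAT", "AttCAT"}
    for i, smiles in enumerate(variants):
        seq = tokenize(smiles)
        ranks = canonical_atom_ranks(smiles)
        prediction, trace = forward_with_trace(model, seq)
        cls = prediction["class_index"] if class_index is None else class_index
        grads = (
            class_gradients(model, seq, cls)
            if grad_methods.intersection(methods)
            else None
        )
        for method in methods:
            att = compute_attribution(
                method, model, seq, class_index=cls, trace=trace, grads=grads,
                seed=seed + i, **method_kwargs,
            )
            out[method].append(
                align_atom_attributions(
                    normalize_attribution(att),
                    seq,
                    ranks,
                    molecule_id=molecule.id,
                    source_smiles=smiles,
                )
            )
    return out


def attribute_augmented(
    model,
    method: str,
    molecule: MoleculeRecord,
    n_augment: int = 10,
    seed: int = 0,
    class_index: int | None = None,
    **method_kwargs,
) -> list[AlignedAtomAttribution]:
    """Attribute the canonical SMILES plus `n_augment` randomized SMILES.

    Returns n_augment + 1 aligned atom attributions (canonical first).
    """
    return attribute_augmented_multi(
        model, [method], molecule, n_augment=n_augment, seed=seed,
        class_index=class_index, **method_kwargs,
    )[method]


# ---------------------------------------------------------------------------
# distances


def cosine_distance(u: np.ndarray, v: np.ndarray) -> float:
    """1 - cos(u, v), in [0, 2]; NaN for a zero vector."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    # a norm product that underflows to zero behaves like a zero vector
    if u.dot(u) * v.dot(v) == 0.0:
        return float("nan")
    return float(_scipy_cosine(u, v))


def pairwise_cosine_matrix(
    atts: list[AlignedAtomAttribution] | list[np.ndarray],
    include_diagonal: bool = False,
) -> tuple[np.ndarray, float]:
    """Full pairwise cosine-distance matrix and its mean (robustness score).

    The mean excludes the structurally-zero diagonal unless
    `include_diagonal=True`; zero-vector entries are NaN, excluded from the
    mean and logged.
    """
    vectors = [a.values if isinstance(a, AlignedAtomAttribution) else np.asarray(a)
               for a in atts]
    if len(vectors) < 2:
        raise ValueError("need at least two vectors")
    lengths = {len(v) for v in vectors}
    if len(lengths) != 1:
        raise ValueError(f"vectors have differing lengths {sorted(lengths)}")
    n = len(vectors)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = cosine_distance(vectors[i], vectors[j])
    mask = ~np.eye(n, dtype=bool) if not include_diagonal else np.ones((n, n), bool)
    entries = mat[mask]
    valid = entries[~np.isnan(entries)]
    if np.isnan(entries).any():
        logger.warning(
            "excluded %d zero-vector distance entries", int(np.isnan(entries).sum())
        )
    score = float(valid.mean()) if valid.size else float("nan")
    return mat, score


def tta_average(atts: list[AlignedAtomAttribution]) -> AlignedAtomAttribution:
    """Arithmetic mean of aligned attributions per canonical atom."""
    if not atts:
        raise ValueError("need at least one attribution")
    lengths = {len(a.values) for a in atts}
    if len(lengths) != 1:
        raise ValueError(f"aligned lengths differ: {sorted(lengths)}")
    stacked = np.stack([a.values for a in atts])
    return AlignedAtomAttribution(
        molecule_id=atts[0].molecule_id,
        source_smiles="tta-average",
        values=stacked.mean(axis=0),
        normalization_base=float(np.mean([a.normalization_base for a in atts])),
    )


# ---------------------------------------------------------------------------
# entropy & relative importance


def attribution_entropy(values: np.ndarray) -> float:
    """Shannon entropy (bits) of the |values| distribution.

    Signed attributions carry no probability interpretation, so the
    absolute values are renormalised to sum 1 first; 0·log0 := 0.
    """
    v = np.abs(np.asarray(values, dtype=float))
    total = v.sum()
    if total == 0:
        return 0.0
    p = v / total
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


COMPONENTS = ("full", "smiles", "atom", "alerts")


def relative_importance(
    att: Attribution,
    seq: TokenSequence,
    component: str,
    alert_atoms: frozenset[int] | set[int] | None = None,
    signed: bool = False,
) -> float:
    """Fraction of the full-string attribution mass in one component.

    Components: `full` (every position, including BOS/EOS/PAD), `smiles`
    (non-special tokens), `atom` (atom tokens) and `alerts` (atom tokens of
    matched structural-alert atoms; requires `alert_atoms`).  Default mass
    is |φ̂_i| so fractions lie in [0, 1] and disjoint components add;
    `signed=True` sums the signed φ̂_i instead.
    """
    if component not in COMPONENTS:
        raise ValueError(f"unknown component {component!r}; choose from {COMPONENTS}")
    if not att.normalized:
        att = normalize_attribution(att)
    if component == "full":
        positions = list(range(len(att.values)))
    elif component == "smiles":
        positions = seq.smiles_positions()
    elif component == "atom":
        positions = seq.atom_positions()
    else:
        if alert_atoms is None:
            raise ValueError("alerts component requires alert_atoms")
        positions = [
            pos for pos in seq.atom_positions()
            if seq.atom_of_token[pos] in alert_atoms
        ]
    mass = att.values[positions]
    return float(mass.sum() if signed else np.abs(mass).sum())


def alert_importance(
    att: Attribution, seq: TokenSequence, smiles: str, alerts: AlertSet,
    signed: bool = False,
) -> float:
    """Relative importance of all structural-alert atoms in one molecule."""
    matches = match_alerts(smiles, alerts)
    return relative_importance(
        att, seq, "alerts", alert_atoms=matches.atom_union, signed=signed
    )


# ---------------------------------------------------------------------------
# cross-group comparisons


def cross_group_distances(
    groups: dict[str, dict[str, AlignedAtomAttribution]],
    axis: str = "model",
) -> RobustnessReport:
    """Pairwise distances across groups (models or methods) per molecule.

    `groups` maps a group key (model name or method name) to a mapping
    molecule_id -> aligned attribution.  Molecules missing from any group
    are skipped with a log message.  Returns a tidy distance table with one
    row per (molecule, group pair).
    """
    if axis not in ("model", "method"):
        raise ValueError("axis must be 'model' or 'method'")
    keys = sorted(groups)
    if len(keys) < 2:
        return RobustnessReport(distances=pd.DataFrame(
            columns=["molecule_id", "group_a", "group_b", "axis", "distance"]
        ))
    shared = set.intersection(*(set(groups[k]) for k in keys))
    skipped = set.union(*(set(groups[k]) for k in keys)) - shared
    for mol in sorted(skipped):
        logger.info("molecule %s missing from some groups; skipped", mol)
    rows = []
    zero_excluded = 0
    for mol in sorted(shared):
        for i, ka in enumerate(keys):
            for kb in keys[i + 1:]:
                d = cosine_distance(groups[ka][mol].values, groups[kb][mol].values)
                if np.isnan(d):
                    zero_excluded += 1
                    continue
                rows.append(
                    {"molecule_id": mol, "group_a": ka, "group_b": kb,
                     "axis": axis, "distance": d}
                )
    frame = pd.DataFrame(rows, columns=["molecule_id", "group_a", "group_b", "axis", "distance"])
    scores = (
        frame.groupby("molecule_id")["distance"].mean().to_dict() if len(frame) else {}
    )
    return RobustnessReport(
        scores=scores, distances=frame, excluded_zero_vectors=zero_excluded
    )
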