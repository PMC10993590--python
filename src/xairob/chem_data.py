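"""Molecule ingestion, cleaning, SMILES enumeration, tokenization and alerts.

All chemistry is delegated to RDKit; this module fixes the conventions the
rest of the package relies on: canonical SMILES as molecule identity,
character-level tokenization with one token per heavy atom, canonical atom
ranks for aligning attributions across SMILES enumerations of the same
molecule, and a seeded generator of small synthetic drug-like molecules
with an optional planted structural alert.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem.Scaffolds import MurckoScaffold

from .vocab import (
    BOS,
    EOS,
    MASK,
    PAD,
    DEFAULT_VOCAB,
    SmilesVocabulary,
    TokenizationError,
)

RDLogger.DisableLog("rdApp.*")  # RDKit parse chatter goes through our log instead

logger = logging.getLogger(__name__)

MAX_SMILES_TOKENS = 175  # SMILES tokens, excluding BOS/EOS/PAD
FULL_STRING_LENGTH = MAX_SMILES_TOKENS + 2


class InvalidStructureError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class MoleculeRecord:
    """One molecule keyed by its canonical SMILES."""

    id: str
    smiles_canonical: str
    label: int | None = None
    source: str = ""


@dataclass(frozen=True)
class TokenSequence:
    """A tokenized full string: BOS + SMILES tokens + EOS (+ PAD)."""

    tokens: tuple[str, ...]
    ids: tuple[int, ...]
    atom_of_token: dict[int, int]  # token position -> heavy-atom index
    vocab: SmilesVocabulary = field(repr=False, default=DEFAULT_VOCAB)

    @property
    def length(self) -> int:
        return len(self.tokens)

    def smiles_positions(self) -> list[int]:
        """Positions of SMILES (non-special) tokens, in order."""
        specials = {BOS, EOS, PAD, MASK}
        return [i for i, t in enumerate(self.tokens) if t not in specials]

    def atom_positions(self) -> list[int]:
        return sorted(self.atom_of_token)

    def detokenize(self) -> str:
        """Reassemble the SMILES string between BOS and EOS."""
        out = []
        for tok in self.tokens[1:]:
            if tok == EOS:
                break
            out.append(tok)
        return "".join(out)


@dataclass(frozen=True)
class AlertSet:
    """Named SMARTS structural alerts, compiled once."""

    entries: tuple[tuple[str, str], ...]
    _patterns: tuple = field(repr=False, default=())

    def __post_init__(self):
        names = [n for n, _ in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("alert names must be unique")
        patterns = []
        for name, smarts in self.entries:
            patt = Chem.MolFromSmarts(smarts)
            if patt is None:
                raise ValueError(f"alert {name!r}: SMARTS {smarts!r} does not compile")
            patterns.append(patt)
        object.__setattr__(self, "_patterns", tuple(patterns))

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AlertSet":
        entries = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, smarts = line.split("\t")
            entries.append((name, smarts))
        return cls(entries=tuple(entries))


@dataclass(frozen=True)
class AlertMatches:
    """All substructure matches of an AlertSet against one molecule."""

    matches: tuple[tuple[str, frozenset[int]], ...]
    atom_union: frozenset[int]


@dataclass(frozen=True)
class MaskingPlan:
    """Ground truth of one masking corruption."""

    selected_positions: frozenset[int]
    action_of_position: dict[int, str]  # position -> MASK | RANDOM | KEEP


@dataclass
class CleaningResult:
    records: list[MoleculeRecord]
    failures: list[dict]


# ---------------------------------------------------------------------------
# cleaning & canonicalization


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidStructureError(f"cannot parse SMILES {smiles!r}")
    return mol


def canonicalize(smiles: str) -> str:
    """Deterministic canonical SMILES; raises on unparseable input."""
    return Chem.MolToSmiles(_mol_from_smiles(smiles))


def _strip_salt(mol: Chem.Mol) -> Chem.Mol:
    """Keep the largest fragment by heavy-atom count.

    Ties are broken by lexicographic order of the fragments' canonical
    SMILES, so the choice is deterministic.
    """
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) <= 1:
        return mol
    keyed = sorted(
        frags, key=lambda f: (-f.GetNumHeavyAtoms(), Chem.MolToSmiles(f))
    )
    return keyed[0]


def clean_structures(
    smiles: Sequence[str],
    labels: Sequence[int | None] | None = None,
    ids: Sequence[str] | None = None,
    source: str = "",
) -> CleaningResult:
    """Clean raw SMILES into deduplicated canonical records.

    Stereochemistry annotations are removed, the largest fragment is kept
    (salt stripping), the molecule is re-sanitized and its canonical SMILES
    becomes the record key.  Exact duplicates collapse to the first
    occurrence; duplicates with conflicting labels are dropped entirely and
    logged.  Unparseable inputs are skipped with a logged reason.
    """
    if labels is None:
        labels = [None] * len(smiles)
    if ids is None:
        ids = [f"mol-{i}" for i in range(len(smiles))]
    by_key: dict[str, MoleculeRecord] = {}
    conflicted: set[str] = set()
    failures: list[dict] = []
    for raw, label, mol_id in zip(smiles, labels, ids):
        try:
            if not raw:
                raise InvalidStructureError("empty SMILES")
            mol = _mol_from_smiles(raw)
            Chem.RemoveStereochemistry(mol)
            mol = _strip_salt(mol)
            Chem.SanitizeMol(mol)
            key = Chem.MolToSmiles(mol)
        except (InvalidStructureError, Chem.rdchem.MolSanitizeException) as exc:
            failures.append({"id": mol_id, "smiles": raw, "reason": str(exc)})
            logger.warning("skipping %s (%r): %s", mol_id, raw, exc)
            continue
        if key in by_key:
            prev = by_key[key]
            if prev.label is not None and label is not None and prev.label != label:
                conflicted.add(key)
            continue
        by_key[key] = MoleculeRecord(
            id=mol_id, smiles_canonical=key, label=label, source=source
        )
    for key in conflicted:
        rec = by_key.pop(key)
        failures.append(
            {"id": rec.id, "smiles": key, "reason": "conflicting duplicate labels"}
        )
        logger.warning("dropping %s: conflicting duplicate labels", key)
    return CleaningResult(records=list(by_key.values()), failures=failures)


def remove_overlap(
    a: Iterable[MoleculeRecord], b: Iterable[MoleculeRecord]
) -> list[MoleculeRecord]:
    """Return records of `b` whose canonical SMILES do not occur in `a`."""
    keys = {rec.smiles_canonical for rec in a}
    return [rec for rec in b if rec.smiles_canonical not in keys]


# ---------------------------------------------------------------------------
# enumeration & canonical ranks


def enumerate_smiles(smiles: str, n: int, seed: int) -> list[str]:
    """`n` randomized-atom-order SMILES of the same molecule.

    Atom order is permuted with a seeded generator and the string written
    non-canonically, so every output canonicalizes back to the input's
    canonical form.  Duplicates are allowed (small molecules admit few
    distinct strings).  Outputs longer than the tokenizer limit are
    resampled; if a molecule cannot fit, an error is raised.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    mol = _mol_from_smiles(smiles)
    rng = np.random.default_rng(seed)
    out: list[str] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 20 * n:
            raise InvalidStructureError(
                f"cannot enumerate {smiles!r} within the length limit"
            )
        perm = rng.permutation(mol.GetNumAtoms()).tolist()
        shuffled = Chem.RenumberAtoms(mol, perm)
        rand = Chem.MolToSmiles(shuffled, canonical=False)
        if len(DEFAULT_VOCAB.split(rand)) <= MAX_SMILES_TOKENS:
            out.append(rand)
    return out


def canonical_atom_ranks(smiles: str) -> list[int]:
    """Canonical rank of each heavy atom, in this string's atom order.

    The rank of a given atom is a property of the molecular graph, not of
    the particular SMILES, so ranks computed on two enumerations of the
    same molecule agree atom-by-atom — the basis for aligning attributions.
    """
    mol = _mol_from_smiles(smiles)
    return list(Chem.CanonicalRankAtoms(mol, breakTies=True))


# ---------------------------------------------------------------------------
# tokenization & masking


def tokenize(
    smiles: str,
    pad_to: int | None = None,
    vocab: SmilesVocabulary = DEFAULT_VOCAB,
) -> TokenSequence:
    """Character-level tokenization with BOS/EOS and optional PAD.

    Two-letter halogens and bracket atoms are single tokens, so
    `atom_of_token` maps exactly one token position to each heavy atom, in
    string order.  `pad_to` is the full padded length including specials.
    """
    toks = vocab.split(smiles)
    if len(toks) > MAX_SMILES_TOKENS:
        raise TokenizationError(
            f"SMILES has {len(toks)} tokens, exceeding the {MAX_SMILES_TOKENS} limit"
        )
    full = [BOS] + toks + [EOS]
    if pad_to is not None:
        if pad_to < len(full):
            raise TokenizationError(
                f"pad_to={pad_to} shorter than sequence length {len(full)}"
            )
        full += [PAD] * (pad_to - len(full))
    atom_of_token: dict[int, int] = {}
    atom_idx = 0
    for pos, tok in enumerate(full):
        if vocab.is_atom_token(tok):
            atom_of_token[pos] = atom_idx
            atom_idx += 1
    return TokenSequence(
        tokens=tuple(full),
        ids=tuple(vocab.encode(full)),
        atom_of_token=atom_of_token,
        vocab=vocab,
    )


MASK_SELECT_P = 0.15
MASK_ACTION_P = {"MASK": 0.80, "RANDOM": 0.10, "KEEP": 0.10}


def mask_tokens(
    seq: TokenSequence, seed: int
) -> tuple[TokenSequence, MaskingPlan]:
    """BERT-style corruption of a token sequence.

    Each non-special position is independently selected with probability
    0.15; a selected position becomes the MASK token with probability 0.80,
    a uniformly random non-special vocabulary token with probability 0.10,
    or stays unchanged with probability 0.10.
    """
    rng = np.random.default_rng(seed)
    vocab = seq.vocab
    candidates = seq.smiles_positions()
    if not candidates:
        raise ValueError("sequence has no non-special tokens to mask")
    tokens = list(seq.tokens)
    selected: list[int] = []
    actions: dict[int, str] = {}
    non_special = vocab.non_special_ids()
    for pos in candidates:
        if rng.random() >= MASK_SELECT_P:
            continue
        selected.append(pos)
        u = rng.random()
        if u < MASK_ACTION_P["MASK"]:
            actions[pos] = "MASK"
            tokens[pos] = MASK
        elif u < MASK_ACTION_P["MASK"] + MASK_ACTION_P["RANDOM"]:
            actions[pos] = "RANDOM"
            tokens[pos] = vocab.tokens[non_special[rng.integers(len(non_special))]]
        else:
            actions[pos] = "KEEP"
    corrupted = TokenSequence(
        tokens=tuple(tokens),
        ids=tuple(vocab.encode(tokens)),
        atom_of_token=dict(seq.atom_of_token),
        vocab=vocab,
    )
    plan = MaskingPlan(
        selected_positions=frozenset(selected), action_of_position=actions
    )
    return corrupted, plan


# ---------------------------------------------------------------------------
# structural alerts


def match_alerts(smiles: str, alerts: AlertSet) -> AlertMatches:
    """All substructure matches of each alert, in this string's atom numbering."""
    mol = _mol_from_smiles(smiles)
    matches: list[tuple[str, frozenset[int]]] = []
    union: set[int] = set()
    for (name, _), patt in zip(alerts.entries, alerts._patterns):
        for match in mol.GetSubstructMatches(patt):
            atom_set = frozenset(match)
            matches.append((name, atom_set))
            union |= atom_set
    return AlertMatches(matches=tuple(matches), atom_union=frozenset(union))


# ---------------------------------------------------------------------------
# synthetic fixtures

NITRO_ALERT_SMARTS = "[N+](=O)[O-]"
NITRO_ALERT_FRAGMENT = "[N+](=O)[O-]"

# chain units: every unit starts and ends with an atom that accepts one
# more single bond, so plain concatenation yields valid SMILES
_CHAIN_UNITS = ["C", "CC", "CCC", "CO", "CN", "CCO", "CCN", "C(C)C", "C(=O)C"]
_RING_UNITS = ["c1ccccc1", "C1CCCCC1", "c1ccncc1", "C1CCOC1", "c1ccsc1"]
_TERMINAL_UNITS = ["F", "Cl", "Br", "O", "N", "C(=O)O", "C#N"]


def generate_synthetic_molecules(
    n: int,
    seed: int,
    planted_alert: str | None = None,
    noise: float = 0.1,
    max_tokens: int = 60,
) -> list[MoleculeRecord]:
    """Seeded corpus of small valid molecules from a fragment grammar.

    Molecules are assembled from alkyl/ether/amine chain units, optional
    rings and a terminal group.  With `planted_alert` given (a fragment
    that is also a valid SMARTS, e.g. a nitro group), about half the
    molecules carry the alert and labels are `contains(alert) XOR
    Bernoulli(noise)` — a separable toxicity surrogate.  Every output is
    valid, cleanable and at most `max_tokens` SMILES tokens long.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    alert_set = (
        AlertSet(entries=(("planted", planted_alert),)) if planted_alert else None
    )
    records: list[MoleculeRecord] = []
    seen: set[str] = set()
    while len(records) < n:
        parts = [rng.choice(_CHAIN_UNITS)]
        for _ in range(rng.integers(1, 4)):
            pool = _RING_UNITS if rng.random() < 0.35 else _CHAIN_UNITS
            parts.append(rng.choice(pool))
        wants_alert = planted_alert is not None and rng.random() < 0.5
        if wants_alert:
            parts.append(NITRO_ALERT_FRAGMENT)
        elif rng.random() < 0.4:
            parts.append(rng.choice(_TERMINAL_UNITS))
        smiles = "".join(parts)
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            continue
        canonical = Chem.MolToSmiles(mol)
        if canonical in seen:
            continue
        if len(DEFAULT_VOCAB.split(canonical)) > max_tokens:
            continue
        seen.add(canonical)
        label: int | None = None
        if alert_set is not None:
            has_alert = bool(match_alerts(canonical, alert_set).matches)
            flip = rng.random() < noise
            label = int(has_alert) ^ int(flip)
        records.append(
            MoleculeRecord(
                id=f"syn-{len(records):04d}",
                smiles_canonical=canonical,
                label=label,
                source="synthetic",
            )
        )
    return records


# ---------------------------------------------------------------------------
# splitting & IO


def scaffold_split(
    records: Sequence[MoleculeRecord],
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> tuple[list[MoleculeRecord], list[MoleculeRecord], list[MoleculeRecord]]:
    """Bemis–Murcko scaffold split: whole scaffold groups per partition.

    Groups are assigned largest-first to train, then validation, then test,
    so test molecules come from scaffolds unseen in training.
    """
    groups: dict[str, list[MoleculeRecord]] = {}
    for rec in records:
        scaffold = MurckoScaffold.MurckoScaffoldSmiles(rec.smiles_canonical)
        groups.setdefault(scaffold, []).append(rec)
    ordered = sorted(groups.values(), key=lambda g: (-len(g), g[0].smiles_canonical))
    n = len(records)
    n_train, n_valid = fractions[0] * n, (fractions[0] + fractions[1]) * n
    train: list[MoleculeRecord] = []
    valid: list[MoleculeRecord] = []
    test: list[MoleculeRecord] = []
    for group in ordered:
        if len(train) + len(group) <= n_train:
            train.extend(group)
        elif len(train) + len(valid) + len(group) <= n_valid:
            valid.extend(group)
        else:
            test.extend(group)
    return train, valid, test


def random_split(
    records: Sequence[MoleculeRecord],
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> tuple[list[MoleculeRecord], list[MoleculeRecord], list[MoleculeRecord]]:
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    n = len(records)
    n_train = int(round(fractions[0] * n))
    n_valid = int(round(fractions[1] * n))
    shuffled = [records[i] for i in order]
    return (
        shuffled[:n_train],
        shuffled[n_train : n_train + n_valid],
        shuffled[n_train + n_valid :],
    )


def read_molecule_table(path: str | Path) -> tuple[list[str], list[int | None], list[str]]:
    """Read a CSV with columns smiles[,label][,id] or a plain .smi file."""
    path = Path(path)
    smiles: list[str] = []
    labels: list[int | None] = []
    ids: list[str] = []
    if path.suffix == ".smi":
        for i, line in enumerate(path.read_text().splitlines()):
            line = line.strip()
            if line:
                smiles.append(line)
                labels.append(None)
                ids.append(f"mol-{i}")
        return smiles, labels, ids
    with open(path, newline="") as fh:
        for i, row in enumerate(csv.DictReader(fh)):
            smiles.append(row["smiles"])
            raw_label = row.get("label")
            labels.append(int(raw_label) if raw_label not in (None, "") else None)
            ids.append(row.get("id") or f"mol-{i}")
    return smiles, labels, ids


def write_records_csv(records: Sequence[MoleculeRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "smiles", "label", "source"])
        for rec in records:
            writer.writerow(
                [rec.id, rec.smiles_canonical,
                 "" if rec.label is None else rec.label, rec.source]
            )
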