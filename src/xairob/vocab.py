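"""Fixed 68-symbol SMILES token vocabulary.

Character-level tokenization in which the two-letter halogens (Cl, Br) and
bracket atoms ([nH], [N+], ...) are kept as single tokens, so that every
heavy atom owns exactly one token — the property the canonical-atom
alignment of attributions depends on.  The table is fixed at 68 codes
(4 specials + 64 SMILES symbols); any character or bracket atom outside it
is a hard error rather than an <unk>, keeping model vocabularies and
checkpoints comparable.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

BOS = "<bos>"
EOS = "<eos>"
PAD = "<pad>"
MASK = "<mask>"
SPECIAL_TOKENS = (BOS, EOS, PAD, MASK)

_ORGANIC_ATOMS = ["B", "C", "N", "O", "P", "S", "F", "I"]
_AROMATIC_ATOMS = ["b", "c", "n", "o", "p", "s"]
_TWO_LETTER = ["Cl", "Br"]
_STRUCTURE = ["=", "#", "-", "/", "\\", ".", ":", "(", ")", "%"]
_DIGITS = [str(d) for d in range(10)]
# curated bracket-atom tokens covering the charged/protonated states that
# survive the cleaning rules (stereochemistry stripped, largest fragment kept)
_BRACKET_ATOMS = [
    "[nH]", "[n+]", "[nH+]", "[N+]", "[N-]", "[NH+]", "[NH2+]", "[NH3+]",
    "[NH-]", "[O-]", "[O+]", "[OH+]", "[o+]", "[S-]", "[S+]", "[s+]",
    "[SH]", "[Se]", "[se]", "[Si]", "[P+]", "[PH]", "[B-]", "[C-]",
    "[C+]", "[CH-]", "[CH2-]", "[I-]",
]

VOCABULARY: tuple[str, ...] = tuple(
    list(SPECIAL_TOKENS)
    + _ORGANIC_ATOMS
    + _AROMATIC_ATOMS
    + _TWO_LETTER
    + _STRUCTURE
    + _DIGITS
    + _BRACKET_ATOMS
)
assert len(VOCABULARY) == 68, len(VOCABULARY)

_ATOM_TOKENS = frozenset(
    _ORGANIC_ATOMS + _AROMATIC_ATOMS + _TWO_LETTER + _BRACKET_ATOMS
)

_TOKEN_RE = re.compile(r"\[[^\]]+\]|Cl|Br|.")


class TokenizationError(ValueError):
    """A SMILES character or bracket atom outside the fixed vocabulary."""


@dataclass(frozen=True)
class SmilesVocabulary:
    """Token <-> integer-code table with special-token bookkeeping."""

    tokens: tuple[str, ...] = VOCABULARY
    index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(
            self, "index", {tok: i for i, tok in enumerate(self.tokens)}
        )

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def bos_id(self) -> int:
        return self.index[BOS]

    @property
    def eos_id(self) -> int:
        return self.index[EOS]

    @property
    def pad_id(self) -> int:
        return self.index[PAD]

    @property
    def mask_id(self) -> int:
        return self.index[MASK]

    @property
    def special_ids(self) -> frozenset[int]:
        return frozenset(self.index[t] for t in SPECIAL_TOKENS)

    def non_special_ids(self) -> list[int]:
        return [i for i in range(len(self.tokens)) if i not in self.special_ids]

    def split(self, smiles: str) -> list[str]:
        """Split a SMILES string into vocabulary tokens (no specials)."""
        toks = _TOKEN_RE.findall(smiles)
        for tok in toks:
            if tok not in self.index:
                raise TokenizationError(
                    f"token {tok!r} in {smiles!r} is outside the fixed vocabulary"
                )
        return toks

    def encode(self, tokens: list[str]) -> list[int]:
        return [self.index[t] for t in tokens]

    @staticmethod
    def is_atom_token(token: str) -> bool:
        return token in _ATOM_TOKENS

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"tokens": list(self.tokens)}, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SmilesVocabulary":
        data = json.loads(Path(path).read_text())
        return cls(tokens=tuple(data["tokens"]))


DEFAULT_VOCAB = SmilesVocabulary()
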