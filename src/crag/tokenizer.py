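"""SMILES tokenization and vocabulary.

Character-level tokenization with a fixed multi-character token table: two-letter
organic-subset elements (Cl, Br), whole bracket atoms ("[nH]", "[C@@H]", ...) and
two-digit ring closures ("%12") are single tokens, longest match first. The
scheme is reversible: ``detokenize(tokenize(s)) == s`` whenever every token of
``s`` is in the vocabulary.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

# longest-match SMILES token pattern; the trailing "." catches any stray
# character so unknown text still tokenizes (to later become UNK)
_TOKEN_RE = re.compile(
    r"(\[[^\]]*\]|Br|Cl|Si|Se|@@|%\d{2}|[BCNOPSFIbcnops]|\(|\)|=|#|-|\+|/|\\|:|~|\*|\$|\.|\d|.)"
)

PAD, BOS, EOS, UNK = "<pad>", "<bos>", "<eos>", "<unk>"
SPECIALS = (PAD, BOS, EOS, UNK)
PAD_ID, BOS_ID, EOS_ID, UNK_ID = 0, 1, 2, 3


def split_smiles(smiles: str) -> list[str]:
    """Split a SMILES string into tokens (no specials added)."""
    return _TOKEN_RE.findall(smiles)


@dataclass(frozen=True)
class Vocabulary:
    """Bijection between SMILES tokens and integer indices.

    Indices 0..3 are reserved for PAD/BOS/EOS/UNK; corpus tokens follow in
    sorted order, so building from the same token set is deterministic and
    order-insensitive.
    """

    tokens: tuple[str, ...]
    index: dict[str, int] = field(default_factory=dict, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "index", {t: i for i, t in enumerate(self.tokens)})

    def __len__(self) -> int:
        return len(self.tokens)

    def __contains__(self, token: str) -> bool:
        return token in self.index

    def id(self, token: str) -> int:
        return self.index.get(token, UNK_ID)

    def token(self, idx: int) -> str:
        return self.tokens[idx]

    def content_hash(self) -> str:
        import hashlib

        return hashlib.sha256("\x00".join(self.tokens).encode()).hexdigest()[:16]


def build_vocabulary(corpus: Iterable[str]) -> Vocabulary:
    """Collect every token in ``corpus`` into a Vocabulary (specials first)."""
    seen: set[str] = set()
    n = 0
    for smiles in corpus:
        n += 1
        seen.update(split_smiles(smiles))
    if n == 0:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    seen -= set(SPECIALS)
    return Vocabulary(tokens=SPECIALS + tuple(sorted(seen)))


@dataclass
class TokenSequence:
    """Integer-encoded SMILES: BOS, tokens..., EOS, then PAD only."""

    indices: list[int]

    @property
    def length(self) -> int:
        """Sequence length excluding padding (BOS/EOS included)."""
        return sum(1 for i in self.indices if i != PAD_ID)

    def __len__(self) -> int:
        return len(self.indices)


def tokenize(
    smiles: str,
    vocab: Vocabulary,
    l_max: int = 60,
    strict: bool = False,
) -> TokenSequence:
    """Encode a SMILES string as [BOS, tokens..., EOS].

    Tokens missing from ``vocab`` become UNK (counted via a warning) unless
    ``strict``, in which case a KeyError is raised. Sequences whose encoded
    length exceeds ``l_max`` raise.
    """
    toks = split_smiles(smiles)
    ids = [BOS_ID]
    n_unk = 0
    for t in toks:
        i = vocab.id(t)
        if i == UNK_ID and t != UNK:
            if strict:
                raise KeyError(f"token {t!r} of {smiles!r} not in vocabulary")
            n_unk += 1
        ids.append(i)
    ids.append(EOS_ID)
    if len(ids) > l_max:
        raise ValueError(f"SMILES {smiles!r} tokenizes to {len(ids)} > l_max={l_max}")
    if n_unk:
        warnings.warn(f"{n_unk} unknown token(s) in {smiles!r} mapped to UNK", stacklevel=2)
    return TokenSequence(indices=ids)


def detokenize(seq: TokenSequence | Sequence[int], vocab: Vocabulary) -> str:
    """Invert ``tokenize``: strip specials, join remaining tokens."""
    indices = seq.indices if isinstance(seq, TokenSequence) else list(seq)
    out: list[str] = []
    for i in indices:
        if i == EOS_ID:
            break
        if i in (PAD_ID, BOS_ID):
            continue
        out.append(vocab.token(i))
    return "".join(out)
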