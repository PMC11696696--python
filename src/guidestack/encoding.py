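"""Stack encoding of aligned sgRNA-DNA duplexes.

A guide and its aligned genomic target are both 23 nt long (20-nt spacer +
3-nt PAM) and are compared position by position in the same-strand
convention: a matched position shows the identical letter in guide and
target.  A sliding window of width *k* (default 2, the "doublet") walks the
duplex 5'->3' with a step of one base; each window yields a token made of
the guide k-mer concatenated with the aligned target k-mer, so a 23-bp pair
becomes ``23 - k + 1`` tokens over a vocabulary of ``4**(2k)`` (256 for
doublets).  The token index is the base-4 value of the concatenated string
with A=0, C=1, G=2, T=3 — lexicographic, reconstructible without a table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DUPLEX_LENGTH = 23
_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}

PAIR_TABLE_COLUMNS = ["guide_id", "guide_seq", "target_seq", "label"]


class InvalidSequenceError(ValueError):
    """A sequence contains a character outside the working alphabet."""


@dataclass(frozen=True)
class GuideTargetPair:
    """One aligned sgRNA-DNA duplex with a binary off-target label.

    ``guide_seq`` and ``target_seq`` are 23-character strings over
    {A,C,G,T}; positions 1-20 are the spacer, 21-23 the PAM.  ``label`` is
    1 for a validated off-target cleavage site, 0 for a negative.
    """

    guide_id: str
    guide_seq: str
    target_seq: str
    label: int

    def __post_init__(self) -> None:
        if len(self.guide_seq) != DUPLEX_LENGTH or len(self.target_seq) != DUPLEX_LENGTH:
            raise InvalidSequenceError(
                f"guide/target must be {DUPLEX_LENGTH} nt, got "
                f"{len(self.guide_seq)}/{len(self.target_seq)} for {self.guide_id!r}"
            )
        for name, seq in (("guide_seq", self.guide_seq), ("target_seq", self.target_seq)):
            bad = [i for i, c in enumerate(seq, start=1) if c not in _BASE_INDEX]
            if bad:
                raise InvalidSequenceError(
                    f"{name} of {self.guide_id!r} has invalid character at position {bad[0]}"
                )
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")


@dataclass(frozen=True)
class EncodingConfig:
    """Stack-encoding order: k=1 singlet, k=2 doublet, k=3 triplet."""

    k: int = 2

    def __post_init__(self) -> None:
        if self.k not in (1, 2, 3):
            raise ValueError(f"encoding order k must be 1, 2 or 3, got {self.k}")

    @property
    def n_tokens_per_pair(self) -> int:
        return DUPLEX_LENGTH - self.k + 1

    @property
    def vocab_size(self) -> int:
        return 4 ** (2 * self.k)


class Vocabulary:
    """Bijection between 2k-letter token strings and integer indices.

    The token string is the guide k-mer followed by the aligned target
    k-mer; its index is the base-4 reading with A=0, C=1, G=2, T=3, which
    coincides with the lexicographic rank among all ``4**(2k)`` tokens.
    """

    def __init__(self, k: int):
        if k not in (1, 2, 3):
            raise ValueError(f"unsupported encoding order k={k}")
        self.k = k
        self.size = 4 ** (2 * k)

    def index_of(self, token: str) -> int:
        if len(token) != 2 * self.k:
            raise ValueError(f"token must have length {2 * self.k}, got {token!r}")
        idx = 0
        for c in token:
            try:
                idx = idx * 4 + _BASE_INDEX[c]
            except KeyError:
                raise InvalidSequenceError(f"invalid character {c!r} in token {token!r}") from None
        return idx

    def decode(self, index: int) -> str:
        if not 0 <= index < self.size:
            raise IndexError(f"token index {index} outside [0, {self.size})")
        letters = []
        for _ in range(2 * self.k):
            letters.append(_BASES[index % 4])
            index //= 4
        return "".join(reversed(letters))

    def token_label(self, index: int) -> str:
        """Render a token as the field's 'XY to ZW' guide-to-target notation."""
        s = self.decode(index)
        return f"{s[: self.k]} to {s[self.k:]}"

    def __len__(self) -> int:
        return self.size

    def __repr__(self) -> str:
        return f"Vocabulary(k={self.k}, size={self.size})"


@dataclass(frozen=True)
class EncodedPair:
    """Integer token sequence for one duplex, length ``23 - k + 1``."""

    guide_id: str
    token_indices: tuple[int, ...]
    label: int


def normalize_sequence(raw: str) -> str:
    """Uppercase a sequence and map RNA U to DNA T.

    Raises :class:`InvalidSequenceError` (with the 1-based offending
    position) if any character outside {A,C,G,T,-} remains.
    """
    if not raw:
        raise InvalidSequenceError("empty sequence")
    norm = raw.upper().replace("U", "T")
    for i, c in enumerate(norm, start=1):
        if c not in "ACGT-":
            raise InvalidSequenceError(f"invalid character {c!r} at position {i}")
    return norm


def build_vocabulary(k: int) -> Vocabulary:
    """Vocabulary of all guide-target k-mer stacks: 16, 256 or 4096 tokens."""
    return Vocabulary(k)


def tokenize_pair(
    pair: GuideTargetPair,
    cfg: EncodingConfig | None = None,
    vocab: Vocabulary | None = None,
) -> EncodedPair:
    """Slide a width-k window over the duplex and emit stacked token indices.

    Token i (1-based) covers guide and target positions i..i+k-1; the step
    is one base, 5'->3'.  A 23-bp pair yields 22 doublet tokens at k=2.
    """
    cfg = cfg or EncodingConfig()
    vocab = vocab or build_vocabulary(cfg.k)
    if vocab.k != cfg.k:
        raise ValueError(f"vocabulary order {vocab.k} != config order {cfg.k}")
    k = cfg.k
    indices = tuple(
        vocab.index_of(pair.guide_seq[i : i + k] + pair.target_seq[i : i + k])
        for i in range(DUPLEX_LENGTH - k + 1)
    )
    return EncodedPair(guide_id=pair.guide_id, token_indices=indices, label=pair.label)


def tokenize_pairs(
    pairs: list[GuideTargetPair], cfg: EncodingConfig | None = None
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Vectorized tokenization of a pair list.

    Returns ``(X, y, guide_ids)`` where ``X`` is an int array of shape
    (n_pairs, 23 - k + 1) and ``y`` the label vector.
    """
    cfg = cfg or EncodingConfig()
    vocab = build_vocabulary(cfg.k)
    if not pairs:
        return (
            np.empty((0, cfg.n_tokens_per_pair), dtype=np.int64),
            np.empty(0, dtype=np.int64),
            [],
        )
    encoded = [tokenize_pair(p, cfg, vocab) for p in pairs]
    X = np.array([e.token_indices for e in encoded], dtype=np.int64)
    y = np.array([e.label for e in encoded], dtype=np.int64)
    return X, y, [e.guide_id for e in encoded]


def mismatch_positions(pair: GuideTargetPair) -> list[int]:
    """Sorted 1-based positions where guide and target letters differ."""
    return [
        i
        for i, (g, t) in enumerate(zip(pair.guide_seq, pair.target_seq), start=1)
        if g != t
    ]


@dataclass
class FilterReport:
    """Row counts dropped at each cleaning stage."""

    n_input: int = 0
    unparseable: int = 0
    ambiguous: int = 0
    indel: int = 0
    duplicate: int = 0
    label_conflicts: int = 0
    n_kept: int = 0
    conflict_keys: list[tuple[str, str]] = field(default_factory=list)

    def as_dict(self) -> dict[str, int]:
        return {
            "n_input": self.n_input,
            "unparseable": self.unparseable,
            "ambiguous": self.ambiguous,
            "indel": self.indel,
            "duplicate": self.duplicate,
            "label_conflicts": self.label_conflicts,
            "n_kept": self.n_kept,
        }


def filter_dataset(rows: list[dict]) -> tuple[list[GuideTargetPair], FilterReport]:
    """Apply the dataset cleaning rules to raw pair-table rows.

    Stages, in order: rows whose sequences contain ambiguity codes (N etc.)
    are dropped and counted under ``ambiguous``; rows containing '-' or
    whose sequences are not 23 nt are indel alignments and dropped; the
    remainder is deduplicated on (guide_seq, target_seq) regardless of
    genomic position.  Duplicates with conflicting labels resolve to label 1
    (positive evidence wins) and are logged.  Each row needs keys
    ``guide_id, guide_seq, target_seq, label``.
    """
    report = FilterReport(n_input=len(rows))
    seen: dict[tuple[str, str], int] = {}  # key -> index into kept
    kept: list[GuideTargetPair] = []

    for row_no, row in enumerate(rows, start=1):
        try:
            guide_id = str(row["guide_id"])
            raw_g = str(row["guide_seq"])
            raw_t = str(row["target_seq"])
            label = int(row["label"])
            if label not in (0, 1):
                raise ValueError(f"label {label} not in {{0,1}}")
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(f"unparseable row {row_no}: {exc}") from exc

        try:
            g = normalize_sequence(raw_g)
            t = normalize_sequence(raw_t)
        except InvalidSequenceError:
            report.ambiguous += 1
            continue

        if "-" in g or "-" in t or len(g) != DUPLEX_LENGTH or len(t) != DUPLEX_LENGTH:
            report.indel += 1
            continue

        key = (g, t)
        if key in seen:
            report.duplicate += 1
            prev = kept[seen[key]]
            if prev.label != label:
                report.label_conflicts += 1
                report.conflict_keys.append(key)
                logger.warning(
                    "conflicting labels for duplicate pair %s/%s; keeping label 1",
                    prev.guide_id,
                    guide_id,
                )
                if prev.label == 0:
                    kept[seen[key]] = GuideTargetPair(prev.guide_id, g, t, 1)
            continue

        seen[key] = len(kept)
        kept.append(GuideTargetPair(guide_id, g, t, label))

    report.n_kept = len(kept)
    return kept, report


def read_pair_table(path) -> list[GuideTargetPair]:
    """Read the standard comma-separated pair table.

    Header ``guide_id,guide_seq,target_seq,label``; extra columns are
    ignored with a warning.  Sequences are normalized (case, U->T).
    """
    df = pd.read_csv(path, dtype={"guide_id": str, "guide_seq": str, "target_seq": str})
    missing = [c for c in PAIR_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"pair table {path} missing columns: {missing}")
    extra = [c for c in df.columns if c not in PAIR_TABLE_COLUMNS and c != "tokens"]
    if extra:
        logger.warning("ignoring extra columns in %s: %s", path, extra)
    pairs = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            pairs.append(
                GuideTargetPair(
                    guide_id=str(row.guide_id),
                    guide_seq=normalize_sequence(str(row.guide_seq)),
                    target_seq=normalize_sequence(str(row.target_seq)),
                    label=int(row.label),
                )
            )
        except (InvalidSequenceError, ValueError) as exc:
            raise ValueError(f"{path} line {row_no}: {exc}") from exc
    return pairs


def write_pair_table(pairs: list[GuideTargetPair], path, tokens: bool = False, k: int = 2) -> None:
    """Write pairs as the standard table; optionally append a ``tokens``
    column of space-separated integers."""
    df = pd.DataFrame(
        {
            "guide_id": [p.guide_id for p in pairs],
            "guide_seq": [p.guide_seq for p in pairs],
            "target_seq": [p.target_seq for p in pairs],
            "label": [p.label for p in pairs],
        }
    )
    if tokens:
        cfg = EncodingConfig(k=k)
        vocab = build_vocabulary(k)
        df["tokens"] = [
            " ".join(map(str, tokenize_pair(p, cfg, vocab).token_indices)) for p in pairs
        ]
    df.to_csv(path, index=False)
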