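"""Positional doublet-frequency analysis of sgRNA-DNA duplexes.

Counts how often each stacked token (guide k-mer paired with target k-mer)
occurs at each sliding-window position across a set of duplexes, ranks the
most frequent tokens, and renders the classic token-by-position heatmap.
Restricting to mismatch tokens (guide half differs from target half)
surfaces the substitution patterns that characterise off-target sites;
without the restriction, matched tokens dominate every ranking.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .encoding import EncodingConfig, GuideTargetPair, Vocabulary, build_vocabulary, tokenize_pair


def _is_matched_token(vocab: Vocabulary, index: int) -> bool:
    s = vocab.decode(index)
    return s[: vocab.k] == s[vocab.k :]


@dataclass
class PositionalDoubletMatrix:
    """Token x position count matrix (4^(2k) rows, 23-k+1 columns)."""

    counts: np.ndarray
    vocab: Vocabulary

    @property
    def n_positions(self) -> int:
        return self.counts.shape[1]

    def total_by_token(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_dataframe(self, tokens: list[str] | None = None) -> pd.DataFrame:
        """Rows labelled 'XY to ZW', columns the 1-based positions."""
        if tokens is None:
            idx = np.flatnonzero(self.total_by_token())
        else:
            idx = np.array([self.vocab.index_of(t) for t in tokens], dtype=int)
        labels = [self.vocab.token_label(i) for i in idx]
        return pd.DataFrame(
            self.counts[idx],
            index=labels,
            columns=[str(p) for p in range(1, self.n_positions + 1)],
        )


def positional_frequency(
    pairs: list[GuideTargetPair],
    cfg: EncodingConfig | None = None,
    mismatch_only: bool = False,
) -> PositionalDoubletMatrix:
    """Tally token occurrences per window position over all pairs.

    Each pair contributes exactly one count per position, so without the
    mismatch restriction every column sums to ``len(pairs)``.  With
    ``mismatch_only`` the rows of fully matched tokens (guide half equal
    to target half) are zeroed before any ranking.
    """
    if not pairs:
        raise ValueError("positional_frequency requires at least one pair")
    cfg = cfg or EncodingConfig()
    vocab = build_vocabulary(cfg.k)
    counts = np.zeros((vocab.size, cfg.n_tokens_per_pair), dtype=np.int64)
    for pair in pairs:
        enc = tokenize_pair(pair, cfg, vocab)
        counts[enc.token_indices, np.arange(len(enc.token_indices))] += 1
    if mismatch_only:
        matched = [i for i in range(vocab.size) if _is_matched_token(vocab, i)]
        counts[matched, :] = 0
    return PositionalDoubletMatrix(counts=counts, vocab=vocab)


def top_k_doublets(matrix: PositionalDoubletMatrix, k_top: int = 50) -> list[str]:
    """Token strings ranked by total count (descending), ties broken
    lexicographically; zero-count tokens never appear."""
    if k_top < 1:
        raise ValueError(f"k_top must be >= 1, got {k_top}")
    totals = matrix.total_by_token()
    nonzero = np.flatnonzero(totals)
    ranked = sorted(nonzero, key=lambda i: (-totals[i], matrix.vocab.decode(i)))
    return [matrix.vocab.decode(i) for i in ranked[:k_top]]


def shared_top_doublets(list_a: list[str], list_b: list[str]) -> tuple[int, set[str]]:
    """Intersection of two top-token lists: (size, members)."""
    shared = set(list_a) & set(list_b)
    return len(shared), shared


def export_heatmap(
    matrix: PositionalDoubletMatrix,
    tokens: list[str],
    path_prefix,
) -> tuple[Path, Path]:
    """Write the heatmap image (<prefix>.png) and its numeric table
    (<prefix>.csv); darker cells mark larger counts."""
    if not tokens:
        raise ValueError("export_heatmap requires a non-empty token selection")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    df = matrix.to_dataframe(tokens)
    table_path = prefix.with_suffix(".csv")
    df.to_csv(table_path)

    fig, ax = plt.subplots(figsize=(0.45 * matrix.n_positions + 2, 0.22 * len(tokens) + 2))
    sns.heatmap(df, cmap="Greys", ax=ax, cbar_kws={"label": "count"})
    ax.set_xlabel("window position")
    ax.set_ylabel("doublet (guide to target)")
    fig.tight_layout()
    image_path = prefix.with_suffix(".png")
    fig.savefig(image_path, dpi=150)
    plt.close(fig)
    return image_path, table_path
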