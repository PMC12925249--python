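"""Gene-signature parsing, GMT reading and resolution against a gene universe.

A signature is a named list of gene symbols, optionally annotated with a
trailing ``+`` (expected up, the default) or ``-`` suffix (expected down).
Before scoring, a signature is *resolved* against the row labels of an
expression matrix under a missing-gene policy:

``impute_zero``
    genes absent from the matrix are assumed unexpressed and behave exactly
    as if an all-zero row had been appended for each of them (the right
    assumption for whole-transcriptome assays whose matrices were filtered
    during preprocessing);
``skip``
    absent genes are assumed unmeasured and are dropped from the score
    (the right assumption for targeted panels such as Xenium or CosMx).
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import (
    ConfigurationError,
    ConflictingSignError,
    FormatError,
    GmtFormatError,
    InvalidSignatureError,
)

#: Characters accepted as a negative suffix: ASCII hyphen-minus and the
#: typographic minus sign occasionally produced by word processors.
NEGATIVE_SUFFIXES = ("-", "−")
POSITIVE_SUFFIX = "+"

VALID_POLICIES = ("impute_zero", "skip")


@dataclass(frozen=True)
class GeneSignature:
    """A named gene set with ordered positive and negative members.

    Parameters
    ----------
    name : str
        Label for the signature; used as column prefix in score tables.
    positive : tuple of str
        Genes expected to be highly expressed in cells matching the signature.
    negative : tuple of str
        Genes expected to be lowly expressed; scored as a separate component
        that is subtracted from the positive component.
    """

    name: str
    positive: tuple[str, ...] = ()
    negative: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.positive and not self.negative:
            raise InvalidSignatureError(
                f"signature {self.name!r} has no genes in either set"
            )
        overlap = set(self.positive) & set(self.negative)
        if overlap:
            raise ConflictingSignError(
                f"signature {self.name!r}: gene(s) {sorted(overlap)} appear in "
                "both the positive and the negative set"
            )
        for sym in (*self.positive, *self.negative):
            if not sym or sym[-1] in NEGATIVE_SUFFIXES or sym[-1] == POSITIVE_SUFFIX:
                raise InvalidSignatureError(
                    f"signature {self.name!r}: symbol {sym!r} is empty or still "
                    "carries a +/- suffix; use parse_signature() for raw tokens"
                )

    @property
    def n_genes(self) -> int:
        return len(self.positive) + len(self.negative)

    def to_tokens(self) -> list[str]:
        """Serialize back to suffixed tokens (positive first, then negative)."""
        return [s + POSITIVE_SUFFIX for s in self.positive] + [
            s + NEGATIVE_SUFFIXES[0] for s in self.negative
        ]


def parse_signature(name: str, tokens: Sequence[str]) -> GeneSignature:
    """Parse a list of suffixed gene tokens into a :class:`GeneSignature`.

    Only the final character of a token is interpreted as a suffix: ``"CD4-"``
    places CD4 in the negative set, ``"CD8A+"`` and the unsuffixed ``"TCF7"``
    place their gene in the positive set. Duplicate symbols within one set
    collapse to a single entry (first occurrence wins); the same symbol with
    conflicting suffixes is an error rather than a silent precedence rule.
    """
    if not tokens:
        raise InvalidSignatureError(f"signature {name!r}: empty token list")
    positive: list[str] = []
    negative: list[str] = []
    seen_pos: set[str] = set()
    seen_neg: set[str] = set()
    for raw in tokens:
        tok = raw.strip()
        if not tok:
            raise InvalidSignatureError(f"signature {name!r}: blank token")
        if tok[-1] in NEGATIVE_SUFFIXES:
            sym, is_neg = tok[:-1], True
        elif tok[-1] == POSITIVE_SUFFIX:
            sym, is_neg = tok[:-1], False
        else:
            sym, is_neg = tok, False
        if not sym:
            raise InvalidSignatureError(
                f"signature {name!r}: token {raw!r} has no gene symbol"
            )
        if is_neg:
            if sym in seen_pos:
                raise ConflictingSignError(
                    f"signature {name!r}: gene {sym!r} appears with both + and - suffixes"
                )
            if sym not in seen_neg:
                seen_neg.add(sym)
                negative.append(sym)
        else:
            if sym in seen_neg:
                raise ConflictingSignError(
                    f"signature {name!r}: gene {sym!r} appears with both + and - suffixes"
                )
            if sym not in seen_pos:
                seen_pos.add(sym)
                positive.append(sym)
    return GeneSignature(name=name, positive=tuple(positive), negative=tuple(negative))


def read_gmt(source) -> list[GeneSignature]:
    """Read gene signatures from a GMT (Gene Matrix Transposed) source.

    ``source`` may be a file path or any iterable of lines (e.g. an open text
    file). Each non-blank line is ``name<TAB>description<TAB>gene1<TAB>...``;
    the description is ignored and +/- suffixes on genes are honored.
    """
    if isinstance(source, (str, os.PathLike)):
        with open(source, "rt", encoding="utf-8") as fh:
            return read_gmt(fh)
    signatures: list[GeneSignature] = []
    names: set[str] = set()
    for lineno, line in enumerate(source, start=1):
        line = line.rstrip("\r\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise GmtFormatError(
                f"line {lineno}: expected at least 3 tab-separated fields "
                f"(name, description, genes...), got {len(fields)}"
            )
        name = fields[0]
        if name in names:
            raise GmtFormatError(f"line {lineno}: duplicate signature name {name!r}")
        names.add(name)
        tokens = [t for t in fields[2:] if t.strip()]
        if not tokens:
            raise GmtFormatError(f"line {lineno}: signature {name!r} lists no genes")
        signatures.append(parse_signature(name, tokens))
    return signatures


@dataclass(frozen=True)
class ResolvedSignature:
    """A signature mapped to matrix row indices under a missing-gene policy.

    ``pos_indices``/``neg_indices`` hold the row indices of the genes found in
    the matrix; ``pos_missing``/``neg_missing`` list the symbols that were not.
    Effective set sizes (``n_pos``/``n_neg``) depend on the policy: under
    ``impute_zero`` missing genes still count (they are scored as zero
    expression), under ``skip`` they do not.
    """

    signature: GeneSignature
    pos_indices: tuple[int, ...]
    neg_indices: tuple[int, ...]
    pos_missing: tuple[str, ...]
    neg_missing: tuple[str, ...]
    policy: str

    @property
    def n_pos(self) -> int:
        if self.policy == "impute_zero":
            return len(self.pos_indices) + len(self.pos_missing)
        return len(self.pos_indices)

    @property
    def n_neg(self) -> int:
        if self.policy == "impute_zero":
            return len(self.neg_indices) + len(self.neg_missing)
        return len(self.neg_indices)

    @property
    def n_missing(self) -> int:
        return len(self.pos_missing) + len(self.neg_missing)

    @property
    def is_scorable(self) -> bool:
        """False when no gene of either set survives resolution."""
        return (self.n_pos + self.n_neg) > 0


def resolve_signature(
    sig: GeneSignature,
    gene_universe: Iterable[str],
    policy: str = "impute_zero",
) -> ResolvedSignature:
    """Map signature symbols to row indices of ``gene_universe``.

    Matching is exact and case-sensitive. ``gene_universe`` must be non-empty
    with unique symbols. Under ``skip`` a signature whose sets are both empty
    after resolution is returned with ``is_scorable == False``; scoring then
    reports the score as undefined (never as 0).
    """
    if policy not in VALID_POLICIES:
        raise ConfigurationError(
            f"unknown missing-gene policy {policy!r}; expected one of {VALID_POLICIES}"
        )
    universe = list(gene_universe)
    if not universe:
        raise FormatError("gene universe is empty")
    index = {}
    for i, g in enumerate(universe):
        if g in index:
            raise FormatError(f"gene universe contains duplicate symbol {g!r}")
        index[g] = i

    def split(symbols: tuple[str, ...]):
        found = tuple(index[s] for s in symbols if s in index)
        missing = tuple(s for s in symbols if s not in index)
        return found, missing

    pos_idx, pos_miss = split(sig.positive)
    neg_idx, neg_miss = split(sig.negative)
    return ResolvedSignature(
        signature=sig,
        pos_indices=pos_idx,
        neg_indices=neg_idx,
        pos_missing=pos_miss,
        neg_missing=neg_miss,
        policy=policy,
    )
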