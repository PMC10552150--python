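"""Identifier (meta) repacking.

Within a chunk, identifiers are tokenized into maximal digit runs and the
text between them.  Tokens identical across the chunk are stored once in the
chunk head; varying digit runs become numeric fields encoded as a baseline
plus progressive differences (zigzag varints); any other varying token is
stored literally per record.  In paired mode, when read2's identifier is
read1's with a single token substituted (the Casava read-number field), only
that substitution is stored.  Chunks whose identifiers do not share a common
token shape degrade to literal per-record storage — compactness is traded
away, byte-exact reconstruction never is.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

from .errors import CorruptionError
from .varint import ByteReader, ByteWriter

__all__ = [
    "tokenize_identifier",
    "derive_layout",
    "encode_numeric_series",
    "decode_numeric_series",
    "MetaLayout",
    "TemplateToken",
    "encode_meta_block",
    "decode_meta_block",
]

_TOKEN_RE = re.compile(r"\d+|\D+")

KIND_CONSTANT = 0
KIND_NUMERIC = 1
KIND_LITERAL = 2

# read2 identifier storage modes
R2_ABSENT = 0
R2_IDENTICAL = 1
R2_SUBSTITUTED = 2
R2_INDEPENDENT = 3


def tokenize_identifier(identifier: str) -> List[str]:
    """Split into maximal digit runs and the text between them.

    The concatenation of the returned tokens is always the input itself.
    """
    return _TOKEN_RE.findall(identifier)


@dataclass
class TemplateToken:
    kind: int
    text: str = ""        # CONSTANT: the shared token text
    baseline: int = 0     # NUMERIC: first record's value
    width: int = 0        # NUMERIC: fixed zero-padded width, 0 = natural form


@dataclass
class MetaLayout:
    tokens: List[TemplateToken] = field(default_factory=list)


def _is_digit_run(tok: str) -> bool:
    return tok[0].isdigit()


def derive_layout(token_lists: Sequence[List[str]]) -> Optional[MetaLayout]:
    """Build the chunk template, or None when shapes differ (literal fallback).

    A digit-run token that varies becomes NUMERIC when either every record
    writes it in natural form (no leading zeros) or every record uses the
    same zero-padded width; otherwise it stays LITERAL so text like ``007``
    survives exactly.
    """
    first = token_lists[0]
    n = len(first)
    kinds0 = [_is_digit_run(t) for t in first]
    for toks in token_lists:
        if len(toks) != n:
            return None
        for t, d in zip(toks, kinds0):
            if _is_digit_run(t) != d:
                return None

    layout = MetaLayout()
    for i in range(n):
        column = [toks[i] for toks in token_lists]
        tok0 = column[0]
        if all(t == tok0 for t in column):
            layout.tokens.append(TemplateToken(KIND_CONSTANT, text=tok0))
            continue
        if kinds0[i]:
            if all(str(int(t)) == t for t in column):
                layout.tokens.append(
                    TemplateToken(KIND_NUMERIC, baseline=int(tok0), width=0)
                )
                continue
            w = len(tok0)
            if all(len(t) == w for t in column):
                layout.tokens.append(
                    TemplateToken(KIND_NUMERIC, baseline=int(tok0), width=w)
                )
                continue
        layout.tokens.append(TemplateToken(KIND_LITERAL))
    return layout


def encode_numeric_series(values: Sequence[int], baseline: int) -> bytes:
    """Progressive-difference coding: zigzag varints of v[i] - v[i-1].

    The baseline (first value) lives in the layout, not the payload.
    """
    if not values or values[0] != baseline:
        raise ValueError("first value must equal the baseline")
    w = ByteWriter()
    prev = baseline
    for v in values[1:]:
        w.svarint(v - prev)
        prev = v
    return w.getvalue()


def decode_numeric_series(r: ByteReader, baseline: int, count: int) -> List[int]:
    values = [baseline]
    v = baseline
    for _ in range(count - 1):
        v += r.svarint()
        values.append(v)
    return values


def _render_numeric(value: int, width: int) -> str:
    return str(value).zfill(width) if width else str(value)


def _write_layout_and_fields(w: ByteWriter, ids: Sequence[str],
                             token_lists: Sequence[List[str]],
                             layout: MetaLayout) -> None:
    w.uvarint(len(layout.tokens))
    for tok in layout.tokens:
        w.u8(tok.kind)
        if tok.kind == KIND_CONSTANT:
            w.prefixed(tok.text.encode("latin-1"))
        elif tok.kind == KIND_NUMERIC:
            w.uvarint(tok.baseline)
            w.u8(tok.width)
    for i, tok in enumerate(layout.tokens):
        if tok.kind == KIND_NUMERIC:
            values = [int(toks[i]) for toks in token_lists]
            w.raw(encode_numeric_series(values, tok.baseline))
        elif tok.kind == KIND_LITERAL:
            for toks in token_lists:
                w.prefixed(toks[i].encode("latin-1"))


def _write_literal_ids(w: ByteWriter, ids: Sequence[str]) -> None:
    for ident in ids:
        w.prefixed(ident.encode("latin-1"))


def _read_ids_from_layout(r: ByteReader, count: int) -> List[str]:
    n_tokens = r.uvarint()
    tokens: List[TemplateToken] = []
    for _ in range(n_tokens):
        kind = r.u8()
        if kind == KIND_CONSTANT:
            tokens.append(TemplateToken(kind, text=r.prefixed().decode("latin-1")))
        elif kind == KIND_NUMERIC:
            baseline = r.uvarint()
            width = r.u8()
            tokens.append(TemplateToken(kind, baseline=baseline, width=width))
        elif kind == KIND_LITERAL:
            tokens.append(TemplateToken(kind))
        else:
            raise CorruptionError(f"unknown meta token kind {kind}")
    columns: List[List[str]] = []
    for tok in tokens:
        if tok.kind == KIND_CONSTANT:
            columns.append([tok.text] * count)
        elif tok.kind == KIND_NUMERIC:
            values = decode_numeric_series(r, tok.baseline, count)
            columns.append([_render_numeric(v, tok.width) for v in values])
        else:
            columns.append([r.prefixed().decode("latin-1") for _ in range(count)])
    return ["".join(col[i] for col in columns) for i in range(count)]


def _read_literal_ids(r: ByteReader, count: int) -> List[str]:
    return [r.prefixed().decode("latin-1") for _ in range(count)]


def _shared_tag_analysis(
    ids1: Sequence[str], ids2: Sequence[str]
) -> Tuple[int, int, str]:
    """Decide whether read2 identifiers derive from read1's.

    Returns (mode, token_index, replacement).  SUBSTITUTED requires every
    pair to differ at the same single token index with the same replacement
    text (the Casava read-number field in practice).
    """
    mode = None
    sub_idx = -1
    sub_text = ""
    for id1, id2 in zip(ids1, ids2):
        if id1 == id2:
            pair_mode = R2_IDENTICAL
        else:
            t1, t2 = tokenize_identifier(id1), tokenize_identifier(id2)
            if len(t1) != len(t2):
                return R2_INDEPENDENT, -1, ""
            diffs = [i for i, (a, b) in enumerate(zip(t1, t2)) if a != b]
            if len(diffs) != 1:
                return R2_INDEPENDENT, -1, ""
            pair_mode = R2_SUBSTITUTED
            idx, rep = diffs[0], t2[diffs[0]]
            if sub_idx == -1:
                sub_idx, sub_text = idx, rep
            elif (idx, rep) != (sub_idx, sub_text):
                return R2_INDEPENDENT, -1, ""
        if mode is None:
            mode = pair_mode
        elif mode != pair_mode:
            return R2_INDEPENDENT, -1, ""
    return (mode if mode is not None else R2_IDENTICAL), sub_idx, sub_text


def encode_meta_block(
    ids1: Sequence[str],
    ids2: Optional[Sequence[str]],
    plus1: Optional[Sequence[str]],
    plus2: Optional[Sequence[str]],
) -> bytes:
    """Encode one chunk's identifiers (and, when needed, literal plus lines).

    ``plus1``/``plus2`` are None when the chunk's plus lines conform to the
    header's recorded style, otherwise the literal plus-line texts to store.
    """
    w = ByteWriter()
    tok1 = [tokenize_identifier(i) for i in ids1]
    layout1 = derive_layout(tok1)

    r2_mode = R2_ABSENT
    sub_idx, sub_text = -1, ""
    if ids2 is not None:
        r2_mode, sub_idx, sub_text = _shared_tag_analysis(ids1, ids2)

    flags = (
        (1 if layout1 is None else 0)
        | (r2_mode << 1)
        | (8 if plus1 is not None else 0)
        | (16 if plus2 is not None else 0)
    )
    r2_layout = None
    tok2 = None
    if r2_mode == R2_INDEPENDENT:
        tok2 = [tokenize_identifier(i) for i in ids2]  # type: ignore[union-attr]
        r2_layout = derive_layout(tok2)
        if r2_layout is None:
            flags |= 32
    w.u8(flags)

    if layout1 is None:
        _write_literal_ids(w, ids1)
    else:
        _write_layout_and_fields(w, ids1, tok1, layout1)

    if r2_mode == R2_SUBSTITUTED:
        w.uvarint(sub_idx)
        w.prefixed(sub_text.encode("latin-1"))
    elif r2_mode == R2_INDEPENDENT:
        if r2_layout is None:
            _write_literal_ids(w, ids2)  # type: ignore[arg-type]
        else:
            _write_layout_and_fields(w, ids2, tok2, r2_layout)  # type: ignore[arg-type]

    if plus1 is not None:
        for p in plus1:
            w.prefixed(p.encode("latin-1"))
    if plus2 is not None:
        for p in plus2:
            w.prefixed(p.encode("latin-1"))
    return w.getvalue()


def decode_meta_block(data: bytes, count: int, paired: bool):
    """Inverse of :func:`encode_meta_block`.

    Returns ``(ids1, ids2, plus1, plus2)``; ids2 is None for single-end
    archives, plus lists are None when the chunk conformed to the header
    style.
    """
    r = ByteReader(data)
    flags = r.u8()
    degraded1 = bool(flags & 1)
    r2_mode = (flags >> 1) & 3
    has_plus1 = bool(flags & 8)
    has_plus2 = bool(flags & 16)
    degraded2 = bool(flags & 32)

    ids1 = _read_literal_ids(r, count) if degraded1 else _read_ids_from_layout(r, count)

    ids2: Optional[List[str]] = None
    if paired:
        if r2_mode == R2_IDENTICAL:
            ids2 = list(ids1)
        elif r2_mode == R2_SUBSTITUTED:
            idx = r.uvarint()
            rep = r.prefixed().decode("latin-1")
            ids2 = []
            for ident in ids1:
                toks = tokenize_identifier(ident)
                if idx >= len(toks):
                    raise CorruptionError("substitution index outside identifier")
                toks[idx] = rep
                ids2.append("".join(toks))
        elif r2_mode == R2_INDEPENDENT:
            ids2 = (
                _read_literal_ids(r, count)
                if degraded2
                else _read_ids_from_layout(r, count)
            )
        else:
            raise CorruptionError("paired archive but meta block has no read2 mode")

    plus1 = [r.prefixed().decode("latin-1") for _ in range(count)] if has_plus1 else None
    plus2 = [r.prefixed().decode("latin-1") for _ in range(count)] if has_plus2 else None
    if not r.at_end():
        raise CorruptionError("trailing bytes in meta block")
    return ids1, ids2, plus1, plus2
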