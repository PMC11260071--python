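"""Amino-acid alphabet and background residue frequencies.

The 20-letter canonical alphabet is fixed package-wide; every module that
indexes residues does so through :data:`AA_ALPHABET` so that frequency
matrices, coupling matrices and synthetic generators share one residue
ordering.

The default background distribution ``q`` is the amino-acid composition of
a large nonredundant protein-sequence database, the conventional prior in
statistical coupling analysis.  A flat 1/20 background is available for
sensitivity checks.
"""

from __future__ import annotations

import numpy as np

#: Canonical residue ordering used for all frequency/coupling matrices.
AA_ALPHABET: str = "ACDEFGHIKLMNPQRSTVWY"

#: Integer code assigned to the gap character (one past the last residue).
GAP_CODE: int = 20

#: Gap character in aligned sequences.
GAP_CHAR: str = "-"

_AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}

# Database amino-acid composition (order matches AA_ALPHABET); values sum to 1.
_NONREDUNDANT_DB_FREQS = np.array(
    [
        0.073, 0.025, 0.050, 0.061, 0.042, 0.072, 0.023, 0.053, 0.064, 0.089,
        0.023, 0.043, 0.052, 0.040, 0.052, 0.073, 0.056, 0.063, 0.013, 0.033,
    ]
)


def background_frequencies(kind: str = "database") -> np.ndarray:
    """Return the background residue distribution ``q`` (length 20, sums to 1).

    Parameters
    ----------
    kind:
        ``"database"`` (default) for the bundled nonredundant-database
        composition, or ``"uniform"`` for a flat 1/20 distribution.
    """
    if kind == "database":
        q = _NONREDUNDANT_DB_FREQS.copy()
    elif kind == "uniform":
        q = np.full(20, 1.0 / 20.0)
    else:
        raise ValueError(f"unknown background kind: {kind!r}")
    return q / q.sum()


def encode_sequence(seq: str) -> np.ndarray:
    """Encode an aligned sequence into integer codes (gap -> GAP_CODE)."""
    return np.array([_AA_INDEX.get(c, GAP_CODE) for c in seq], dtype=np.int8)


def decode_codes(codes: np.ndarray) -> str:
    """Inverse of :func:`encode_sequence`."""
    lookup = AA_ALPHABET + GAP_CHAR
    return "".join(lookup[c] for c in codes)
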