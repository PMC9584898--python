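"""The PAM120 amino-acid substitution matrix.

The screen calls two aligned, non-identical residues "highly similar" when
their PAM120 score is strictly greater than 1 — e.g. Glu/Gln (2) and
Tyr/Phe (4) qualify, while Ile/Leu (1) and Ile/Phe (0) do not.  The table
below is the standard published PAM120 matrix restricted to the 20 standard
residues; every other code (B, Z, X, U, O, terminus padding) scores as a
sentinel far below any similarity threshold.
"""

from __future__ import annotations

RESIDUE_ORDER = "ARNDCQEGHILKMFPSTWYV"

_ROWS = """\
 3 -3 -1  0 -3 -1  0  1 -3 -1 -3 -2 -2 -4  1  1  1 -7 -4  0
-3  6 -1 -3 -4  1 -3 -4  1 -2 -4  2 -1 -5 -1 -1 -2  1 -5 -3
-1 -1  4  2 -5  0  1  0  2 -2 -4  1 -3 -4 -2  1  0 -4 -2 -3
 0 -3  2  5 -7  1  3  0  0 -3 -5 -1 -4 -7 -3  0 -1 -8 -5 -3
-3 -4 -5 -7  9 -7 -7 -4 -4 -3 -7 -7 -6 -6 -4  0 -3 -8 -1 -3
-1  1  0  1 -7  6  2 -3  3 -3 -2  0 -1 -6  0 -2 -2 -6 -5 -3
 0 -3  1  3 -7  2  5 -1 -1 -3 -4 -1 -3 -7 -2 -1 -2 -8 -5 -3
 1 -4  0  0 -4 -3 -1  5 -4 -4 -5 -3 -4 -5 -2  1 -1 -8 -6 -2
-3  1  2  0 -4  3 -1 -4  7 -4 -3 -2 -4 -3 -1 -2 -3 -3 -1 -3
-1 -2 -2 -3 -3 -3 -3 -4 -4  6  1 -3  1  0 -3 -2  0 -6 -2  3
-3 -4 -4 -5 -7 -2 -4 -5 -3  1  5 -4  3  0 -3 -4 -3 -3 -2  1
-2  2  1 -1 -7  0 -1 -3 -2 -3 -4  5  0 -7 -2 -1 -1 -5 -5 -4
-2 -1 -3 -4 -6 -1 -3 -4 -4  1  3  0  8 -1 -3 -2 -1 -6 -4  1
-4 -5 -4 -7 -6 -6 -7 -5 -3  0  0 -7 -1  8 -5 -3 -4 -1  4 -3
 1 -1 -2 -3 -4  0 -2 -2 -1 -3 -3 -2 -3 -5  6  1 -1 -7 -6 -2
 1 -1  1  0  0 -2 -1  1 -2 -2 -4 -1 -2 -3  1  3  2 -2 -3 -2
 1 -2  0 -1 -3 -2 -2 -1 -3  0 -3 -1 -1 -4 -1  2  4 -6 -3  0
-7  1 -4 -8 -8 -6 -8 -8 -3 -6 -3 -5 -6 -1 -7 -2 -6 12 -2 -8
-4 -5 -2 -5 -1 -5 -5 -6 -1 -2 -2 -5 -4  4 -6 -3 -3 -2  8 -3
 0 -3 -3 -3 -3 -3 -3 -2 -3  3  1 -4  1 -3 -2 -2  0 -8 -3  5
"""

#: score assigned to any pair involving a code outside the 20-residue table;
#: guaranteed to fall below any sensible similarity threshold
SENTINEL_SCORE = -128


def _build() -> dict[tuple[str, str], int]:
    table: dict[tuple[str, str], int] = {}
    for a, row in zip(RESIDUE_ORDER, _ROWS.strip("\n").split("\n")):
        values = [int(v) for v in row.split()]
        assert len(values) == 20
        for b, v in zip(RESIDUE_ORDER, values):
            table[(a, b)] = v
    # the published matrix is symmetric; fail loudly if the transcription is not
    for a in RESIDUE_ORDER:
        for b in RESIDUE_ORDER:
            assert table[(a, b)] == table[(b, a)], (a, b)
    return table


PAM120: dict[tuple[str, str], int] = _build()


def pam120_score(a: str, b: str) -> int:
    """Symmetric PAM120 score of two one-letter codes.

    Codes absent from the table fall through to :data:`SENTINEL_SCORE`.
    """
    return PAM120.get((a, b), SENTINEL_SCORE)
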