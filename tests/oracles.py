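"""Independent brute-force oracles used by the test suite.

These deliberately use different algorithms from the package: alignment
scores come from explicit enumeration of every global alignment (lattice
path), and motif counts from expanding the IUPAC word set and comparing
every window.  They are only feasible at tiny sizes, which is the point.
"""

from functools import lru_cache
from itertools import product

from vitisugar.alignment import ScoringScheme
from vitisugar.motifs import IUPAC
from vitisugar.promoters import reverse_complement


@lru_cache(maxsize=None)
def _paths(n: int, m: int) -> tuple[str, ...]:
    """All monotone lattice paths from (0,0) to (n,m) as move strings:
    D = aligned pair, U = gap in b, L = gap in a."""
    if n == 0 and m == 0:
        return ("",)
    out = []
    if n > 0 and m > 0:
        out += ["D" + p for p in _paths(n - 1, m - 1)]
    if n > 0:
        out += ["U" + p for p in _paths(n - 1, m)]
    if m > 0:
        out += ["L" + p for p in _paths(n, m - 1)]
    return tuple(out)


def align_score_oracle(a: str, b: str, s: ScoringScheme) -> float:
    """Optimal global affine-gap score by scoring every possible alignment.

    A gap run of length L costs gap_open + (L-1)*gap_extend; end gaps
    are penalized like any other.
    """
    best = -float("inf")
    for path in _paths(len(a), len(b)):
        i = j = 0
        score = 0.0
        prev = ""
        for move in path:
            if move == "D":
                score += s.pair_score(a[i], b[j])
                i += 1
                j += 1
            else:
                score += s.gap_extend if move == prev else s.gap_open
                if move == "U":
                    i += 1
                else:
                    j += 1
            prev = move
        best = max(best, score)
    return best


def expand_iupac(iupac: str) -> set[str]:
    return {"".join(w) for w in product(*(sorted(IUPAC[c]) for c in iupac))}


def count_oracle(sequence: str, iupac: str, strands: str = "forward") -> int:
    """Window-by-window comparison against the expanded word set."""
    words = expand_iupac(iupac)
    k = len(iupac)

    def fwd(seq):
        return sum(1 for i in range(len(seq) - k + 1) if seq[i:i + k] in words)

    n = fwd(sequence)
    if strands == "both":
        n += fwd(reverse_complement(sequence))
    return n
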