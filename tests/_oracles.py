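"""Independent reference implementations used only to check the package."""

import sys
from functools import lru_cache

sys.setrecursionlimit(100_000)


@lru_cache(maxsize=None)
def osa_oracle(a: str, b: str) -> int:
    """Recursive optimal-string-alignment distance, straight from the
    recurrence: insert, delete, substitute, adjacent transposition, each
    substring edited at most once. Kept independent of the package's
    iterative implementation."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    best = min(
        osa_oracle(a[:-1], b) + 1,               # delete from a
        osa_oracle(a, b[:-1]) + 1,               # insert into a
        osa_oracle(a[:-1], b[:-1]) + (a[-1] != b[-1]),
    )
    if len(a) >= 2 and len(b) >= 2 and a[-1] == b[-2] and a[-2] == b[-1]:
        best = min(best, osa_oracle(a[:-2], b[:-2]) + 1)
    return best


def all_strings(alphabet: str, max_len: int):
    """All strings over ``alphabet`` of length 0..max_len."""
    out = [""]
    frontier = [""]
    for _ in range(max_len):
        frontier = [s + c for s in frontier for c in alphabet]
        out.extend(frontier)
    return out
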