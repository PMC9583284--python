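"""String comparison primitives used by the probabilistic linkage.

The Jaro and Jaro-Winkler comparators measure agreement between short
identifier strings (names) as the proportion of matching characters and
character transpositions, with the Winkler variant boosting similarity for
strings sharing a common prefix. Names that are similar but not identical
receive partial agreement weight in the match score.
"""

from __future__ import annotations

__all__ = ["jaro_similarity", "jaro_winkler_similarity"]


def jaro_similarity(s1: str, s2: str) -> float:
    """Jaro similarity between two strings, in [0, 1].

    Characters match if equal and within ``max(len1, len2) // 2 - 1``
    positions of each other; transpositions are matched characters that
    appear in a different order.
    """
    if s1 == s2:
        return 1.0
    len1, len2 = len(s1), len(s2)
    if len1 == 0 or len2 == 0:
        return 0.0
    window = max(max(len1, len2) // 2 - 1, 0)

    flags1 = [False] * len1
    flags2 = [False] * len2
    n_match = 0
    for i, c in enumerate(s1):
        lo = max(0, i - window)
        hi = min(len2, i + window + 1)
        for j in range(lo, hi):
            if not flags2[j] and s2[j] == c:
                flags1[i] = True
                flags2[j] = True
                n_match += 1
                break
    if n_match == 0:
        return 0.0

    # transpositions: compare matched characters in order of appearance
    matched2 = [c for c, f in zip(s2, flags2) if f]
    n_trans = sum(
        1
        for c, m in zip((c for c, f in zip(s1, flags1) if f), matched2)
        if c != m
    )
    half_trans = n_trans // 2

    return (
        n_match / len1 + n_match / len2 + (n_match - half_trans) / n_match
    ) / 3.0


def jaro_winkler_similarity(
    s1: str, s2: str, prefix_scale: float = 0.1, max_prefix: int = 4
) -> float:
    """Jaro-Winkler similarity: Jaro boosted by a shared-prefix bonus.

    ``jw = jaro + l * prefix_scale * (1 - jaro)`` where ``l`` is the length
    of the common prefix, capped at ``max_prefix``.
    """
    if not 0.0 <= prefix_scale <= 0.25:
        raise ValueError("prefix_scale must be in [0, 0.25]")
    jaro = jaro_similarity(s1, s2)
    prefix = 0
    for a, b in zip(s1[:max_prefix], s2[:max_prefix]):
        if a != b:
            break
        prefix += 1
    return jaro + prefix * prefix_scale * (1.0 - jaro)
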