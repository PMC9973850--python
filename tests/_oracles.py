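"""Independent oracles used to cross-check the implementation.

These are deliberately written as flat, literal transcriptions of the
published decision rules and closed-form combinatorics, separate from the
production code paths they validate.
"""

from math import comb


def literal_rule_classifier(pdt_s, pdt_g1, pdt_g2, pdt_f1, pdt_f2,
                            alien=30.0, well=80.0, genus_native=70.0,
                            family_native=40.0):
    """Flat transcription of the published species→genus→family prose rules.

    All five PDTs must be defined (the grid oracle covers that regime).
    """
    if pdt_s < alien:
        return "alien_recent"
    if pdt_s > well:
        if pdt_g2 < alien:
            return "alien_ancestral_species"
        if pdt_f2 < alien:
            return "alien_ancestral_genus"
        if pdt_f2 > family_native:
            return "native"
        return "ambiguous"
    if pdt_g1 < alien:
        return "alien_recent"
    if pdt_g1 > genus_native:
        return "native"
    if pdt_f1 < alien:
        return "alien_recent"
    if pdt_f1 > family_native:
        return "native"
    return "ambiguous"


def hypergeom_upper_tail(N, K, n, k):
    """Exact P[X >= k] for X ~ Hypergeometric(N, K, n) via binomial sums."""
    denom = comb(N, n)
    return sum(comb(K, j) * comb(N - K, n - j)
               for j in range(k, min(K, n) + 1)) / denom


def hypergeom_pmf(N, K, n, j):
    return comb(K, j) * comb(N - K, n - j) / comb(N, n)
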