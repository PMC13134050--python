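"""Published per-group diversity summaries used as recomputation inputs.

A published diversity table row (n, S, Watterson's theta, pi) is
overdetermined: theta_w = S / (a1 * L) pins down the analyzed length L,
and pi * L times the number of sequence pairs is an integer count of
pairwise differences.  ``reconstruct_tajima_row`` exploits this to
recompute Tajima's D (and its significance call) from a printed row
without access to the underlying sequences — a consistency check of the
whole statistics stack against published values.

``JOMON_DIVERSITY_ROWS`` carries the published non-coding-region summary
for the Jomon site/region groups and the two present-day comparison
panels (CHB, JPT): per-group ``(n, S, theta_w, pi, tajima_d, significant)``
with D ``None`` where the published table reports NA (n = 3 groups).
"""

from __future__ import annotations

from .stats import TajimaConstants, tajima_significance, tajimas_d_from_summary

__all__ = ["JOMON_DIVERSITY_ROWS", "reconstruct_tajima_row"]

#: group -> (n, S, theta_w, pi, published D or None, published significance)
JOMON_DIVERSITY_ROWS: dict[str, tuple] = {
    "Iyai": (7, 10, 0.00376, 0.00279, -1.35933, False),
    "Higashimyo": (3, 7, 0.00441, 0.00439, None, None),
    "Odake": (4, 6, 0.00301, 0.00305, 0.17969, False),
    "Kikumatenaga": (4, 6, 0.00301, 0.00305, 0.17969, False),
    "Gionbara": (3, 4, 0.00245, 0.00244, None, None),
    "Saihiro": (6, 9, 0.00363, 0.00293, -1.12062, False),
    "Ichihara": (13, 13, 0.00387, 0.00286, -1.04304, False),
    "Eastern Jomon": (26, 27, 0.00664, 0.00310, -1.93676, True),
    "Western Jomon": (14, 15, 0.00455, 0.00314, -1.25619, False),
    "All": (40, 31, 0.00712, 0.00330, -1.82472, True),
    "CHB": (103, 127, 0.02389, 0.00884, -2.08002, True),
    "JPT": (104, 111, 0.02066, 0.00785, -1.99075, True),
}


def reconstruct_tajima_row(n: int, S: int, theta_w: float, pi: float) -> dict:
    """Recompute L, mean pairwise differences, Tajima's D and significance
    from a published (n, S, theta_w, pi) summary.

    ``L`` is back-calculated from Watterson's estimator and rounded to the
    nearest integer; the total pairwise-difference count is rounded to the
    nearest integer consistent with ``pi`` at that L (pairwise counts are
    integers by construction).
    """
    if S < 1 or n < 2:
        raise ValueError("reconstruction needs n >= 2 and S >= 1")
    const = TajimaConstants.from_n(n)
    L = round(S / (const.a1 * theta_w))
    pairs = n * (n - 1) // 2
    total_diffs = round(pi * pairs * L)
    k = total_diffs / pairs
    d = tajimas_d_from_summary(n, S, k)
    return {
        "L": L,
        "mean_pairwise_differences": k,
        "theta_w": S / (const.a1 * L),
        "pi": k / L,
        "tajima_d": d,
        "significant": tajima_significance(d, n),
    }
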