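"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as plain loops over the published conventions
(module docstrings of riboplast.quantify / riboplast.pausing) without reusing
any implementation code, so an agreement is a genuine dual-route check.
"""

from __future__ import annotations

import math


def assign_oracle(footprints, orfs):
    """All-pairs containment assignment oracle.

    footprints: iterable of (seq_id, five_prime, strand); orfs: iterable of
    OrfRecord-likes. Returns a list of gene ids (None when unassigned),
    applying the rule: ORF containing the 5' end on the same strand, choosing
    the nearest-upstream start codon in gene orientation, ties by smaller
    gene id.
    """
    out = []
    for seq_id, fp5, strand in footprints:
        candidates = []
        for orf in orfs:
            if orf.seq_id != seq_id or orf.strand != strand:
                continue
            if not (orf.start <= fp5 < orf.end):
                continue
            dist = fp5 - orf.start if strand == "+" else (orf.end - 1) - fp5
            candidates.append((dist, orf.gene_id))
        out.append(min(candidates)[1] if candidates else None)
    return out


def smooth_oracle(values, window):
    """Centred truncated moving average by direct enumeration."""
    h = (window - 1) // 2
    n = len(values)
    out = []
    for i in range(n):
        lo, hi = max(0, i - h), min(n, i + h + 1)
        out.append(sum(values[lo:hi]) / (hi - lo))
    return out


def _local_maxima_oracle(v):
    n = len(v)
    if n == 0 or all(x == v[0] for x in v):
        return []
    out = []
    for i in range(n):
        # plateau representative: 5'-most equal value
        if i > 0 and v[i - 1] == v[i]:
            continue
        # walk right over the plateau
        j = i
        while j + 1 < n and v[j + 1] == v[i]:
            j += 1
        left_ok = i == 0 or v[i - 1] < v[i]
        right_ok = j == n - 1 or v[j + 1] < v[i]
        if left_ok and right_ok:
            out.append(i)
    return out


def _prominence_oracle(v, p):
    n = len(v)
    sides = []
    if p > 0:
        m = math.inf
        found = False
        for k in range(p - 1, -1, -1):
            if v[k] > v[p]:
                found = True
                break
            m = min(m, v[k])
        sides.append(m)
    if p < n - 1:
        m = math.inf
        for k in range(p + 1, n):
            if v[k] > v[p]:
                break
            m = min(m, v[k])
        sides.append(m)
    if not sides:
        return v[p]
    return v[p] - max(sides)


def call_peaks_oracle(codon_density, smooth, prom_frac, min_sep, top_k):
    """O(n^2) reimplementation of the full peak-calling contract.

    Returns a sorted list of (codon0, height) tuples, 5'->3'.
    """
    v = smooth_oracle(list(codon_density), smooth)
    if not v or max(v) == min(v):
        return []
    gmax = max(v)
    cands = [
        c for c in _local_maxima_oracle(v)
        if _prominence_oracle(v, c) >= prom_frac * gmax
    ]
    kept = []
    for c in sorted(cands, key=lambda c: (-v[c], c)):
        if all(abs(c - k) >= min_sep for k in kept):
            kept.append(c)
    kept = sorted(kept, key=lambda c: (-v[c], c))[:top_k]
    return sorted((c, v[c]) for c in kept)


def cp_rpkm_oracle(counts_by_gene_sample, lengths):
    """Spreadsheet-style cpRPKM: counts_by_gene_sample is
    {(gene, sample): n}, lengths {gene: L_nt}. Returns the same mapping with
    cpRPKM values."""
    totals = {}
    for (gene, sample), n in counts_by_gene_sample.items():
        totals[sample] = totals.get(sample, 0) + n
    out = {}
    for (gene, sample), n in counts_by_gene_sample.items():
        out[(gene, sample)] = n / ((lengths[gene] / 1000) * (totals[sample] / 1e6))
    return out
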