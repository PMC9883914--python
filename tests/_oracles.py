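"""Brute-force reference implementations used only to cross-check the package.

These enumerate every MAT group and every window directly, with no shared
code with the production implementations in ``heterokaryon``.
"""

from __future__ import annotations

REF, ALT, MISSING = 0, 1, -1


def brute_discordant_flags(calls, mats):
    """calls: list of per-nucleus lists over sites; mats: per-nucleus labels."""
    n_sites = len(calls[0])
    flags = []
    for s in range(n_sites):
        disc = False
        for mat in set(mats):
            seen = {calls[i][s] for i in range(len(mats)) if mats[i] == mat}
            if REF in seen and ALT in seen:
                disc = True
        flags.append(disc)
    return flags


def brute_blocks(contigs, flags, min_run=5, min_snps_per_contig=2):
    """All maximal runs of >= min_run discordant flags, checked window by window.

    Returns (contig, first_local_index, last_local_index) triples, where the
    local index counts sites within the contig.
    """
    out = []
    per_contig = {}
    for c, f in zip(contigs, flags):
        per_contig.setdefault(c, []).append(f)
    for contig, fl in per_contig.items():
        if len(fl) < min_snps_per_contig:
            continue
        n = len(fl)
        for i in range(n):
            for j in range(i, n):
                window = fl[i : j + 1]
                if not all(window):
                    continue
                left_ok = i == 0 or not fl[i - 1]
                right_ok = j == n - 1 or not fl[j + 1]
                if left_ok and right_ok and (j - i + 1) >= min_run:
                    out.append((contig, i, j))
    return sorted(out)
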