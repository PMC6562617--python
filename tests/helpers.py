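"""Shared test helpers (kept importable from any test module)."""

from pedscout.core import GenotypeCall, Variant


def make_variant(states, consequence="missense_variant", chrom="27", pos=37_468_611,
                 samples=("CASE1", "CASE2", "SIRE", "DAM", "SIB1")):
    """Variant with genotype states given as a compact string like 'AAHHR'.

    Codes: A=hom-alt, H=het, R=hom-ref, M=missing (spaces ignored).
    """
    code = {"A": GenotypeCall.HOM_ALT, "H": GenotypeCall.HET,
            "R": GenotypeCall.HOM_REF, "M": GenotypeCall.MISSING}
    states = states.replace(" ", "")
    return Variant(
        chrom=chrom, pos=pos, ref="G", alt="A", consequence=consequence,
        genotypes={s: code[c] for s, c in zip(samples, states)},
    )


def brute_force_roh(positions, calls, params):
    """Independent exhaustive ROH oracle: evaluates every window and marker
    state from scratch with no incremental bookkeeping.

    Returns (start, end, n_snp) tuples.
    """
    n = len(calls)
    w = params.window_snp
    if n < w:
        return []
    window_hom = []
    for s in range(n - w + 1):
        win = calls[s : s + w]
        n_het = sum(1 for c in win if c == 1)
        n_mis = sum(1 for c in win if c == -1)
        hom = n_het <= params.window_het and n_mis <= params.window_missing
        if params.enforce_window_kb and positions[s + w - 1] - positions[s] > params.window_kb * 1000:
            hom = False
        window_hom.append(hom)
    in_state = []
    for j in range(n):
        spanning = [
            window_hom[s]
            for s in range(len(window_hom))
            if s <= j <= s + w - 1
        ]
        in_state.append(sum(spanning) / len(spanning) >= params.window_threshold)
    segments = []
    i = 0
    while i < n:
        if not in_state[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and in_state[j + 1]:
            j += 1
        piece_start = i
        pieces = []
        for k in range(i, j):
            if positions[k + 1] - positions[k] > params.gap_kb * 1000:
                pieces.append((piece_start, k))
                piece_start = k + 1
        pieces.append((piece_start, j))
        for a, b in pieces:
            n_snp = b - a + 1
            length = positions[b] - positions[a]
            if (
                n_snp >= params.min_snp
                and length >= params.min_kb * 1000
                and length / n_snp <= params.density_kb * 1000
            ):
                segments.append((int(positions[a]), int(positions[b]), n_snp))
        i = j + 1
    return segments
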