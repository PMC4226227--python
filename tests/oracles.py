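"""Independent brute-force oracles used to cross-check the implementation.

These deliberately share no code path with the package internals: counting
is done by explicit window-pair comparison with reverse complementation,
and maximal repeats by testing every repeated substring for single-base
extensibility over the doubled (both-strand) text.
"""

from collections import defaultdict

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))


def _windows(genome, k):
    """All N-free forward windows as (contig index, start, string)."""
    out = []
    for ci, c in enumerate(genome):
        s = c.residues
        for i in range(len(s) - k + 1):
            w = s[i : i + k]
            if "N" not in w:
                out.append((ci, i, w))
    return out


def naive_kmer_counts(genome, k):
    """Canonical k-mer counts by pairwise window comparison with explicit RC."""
    wins = _windows(genome, k)
    counts = {}
    for _, _, w in wins:
        canon = min(w, rc(w))
        if canon in counts:
            continue
        counts[canon] = sum(1 for _, _, v in wins if v == w or v == rc(w))
    return counts


def naive_copy_histogram(genome, k):
    counts = naive_kmer_counts(genome, k)
    hist = defaultdict(int)
    for c in counts.values():
        hist[c] += 1
    return dict(hist), len(_windows(genome, k))


def naive_read_fraction(genome, k):
    wins = _windows(genome, k)
    counts = naive_kmer_counts(genome, k)
    rep = sum(1 for _, _, w in wins if counts[min(w, rc(w))] >= 2)
    return rep / len(wins)


def naive_region_fraction(genome, k):
    counts = naive_kmer_counts(genome, k)
    flagged = 0
    non_n = 0
    for ci, c in enumerate(genome):
        s = c.residues
        non_n += sum(1 for ch in s if ch != "N")
        cover = [False] * len(s)
        for i in range(len(s) - k + 1):
            w = s[i : i + k]
            if "N" not in w and counts[min(w, rc(w))] >= 2:
                for j in range(i, i + k):
                    cover[j] = True
        flagged += sum(cover)
    return flagged / non_n


def naive_unmappable_mask(genome, k):
    counts = naive_kmer_counts(genome, k)
    masks = {}
    for c in genome:
        s = c.residues
        cover = [False] * len(s)
        for i in range(len(s) - k + 1):
            w = s[i : i + k]
            if "N" not in w and counts[min(w, rc(w))] >= 2:
                for j in range(i, i + k):
                    cover[j] = True
        masks[c.name] = cover
    return masks


def brute_maximal_repeats(genome, min_len=2, min_copies=2):
    """Maximal repeats over both-strand text, by explicit extension testing.

    Returns {canonical unit: set of (contig, start, end) forward loci}.
    A repeated substring is maximal iff its occurrences do not all share the
    same left character nor all the same right character, with string
    boundaries and N positions acting as unique characters.
    """
    strings = []  # (contig name, strand, sequence, contig length)
    for c in genome:
        strings.append((c.name, "+", c.residues, c.length))
        strings.append((c.name, "-", rc(c.residues), c.length))

    results = {}
    d = min_len
    while True:
        occ = defaultdict(list)
        for si, (_, _, s, _) in enumerate(strings):
            for i in range(len(s) - d + 1):
                sub = s[i : i + d]
                if "N" not in sub:
                    occ[sub].append((si, i))
        repeated = {sub: pos for sub, pos in occ.items() if len(pos) >= 2}
        if not repeated:
            break
        for sub, positions in repeated.items():
            lefts, rights = set(), set()
            for tag, (si, i) in enumerate(positions):
                s = strings[si][2]
                lefts.add(s[i - 1] if i > 0 and s[i - 1] != "N" else f"u{tag}")
                rights.add(
                    s[i + d] if i + d < len(s) and s[i + d] != "N" else f"u{tag}"
                )
            if len(lefts) < 2 or len(rights) < 2:
                continue
            loci = set()
            for si, i in positions:
                name, strand, _, clen = strings[si]
                if strand == "+":
                    loci.add((name, i, i + d))
                else:
                    loci.add((name, clen - i - d, clen - i))
            if len(loci) < min_copies:
                continue
            canon = min(sub, rc(sub))
            if canon not in results:
                results[canon] = loci
        d += 1
    return results


def brute_hamming_components(genome, k, M):
    """Connected components of canonical k-mer types at strand-aware
    Hamming distance <= M, via explicit all-pairs comparison and BFS."""
    counts = naive_kmer_counts(genome, k)
    types = sorted(counts)

    def dist(a, b):
        h = sum(x != y for x, y in zip(a, b))
        hr = sum(x != y for x, y in zip(a, rc(b)))
        return min(h, hr)

    adj = {t: [] for t in types}
    for i, a in enumerate(types):
        for b in types[i + 1 :]:
            if dist(a, b) <= M:
                adj[a].append(b)
                adj[b].append(a)
    seen = set()
    comps = []
    for t in types:
        if t in seen:
            continue
        comp, queue = set(), [t]
        while queue:
            u = queue.pop()
            if u in comp:
                continue
            comp.add(u)
            queue.extend(v for v in adj[u] if v not in comp)
        seen |= comp
        comps.append(frozenset(comp))
    return comps, counts
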