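"""RNA secondary-structure prediction and the randomisation (randfold) test.

Folding delegates to the ViennaRNA thermodynamic engine; the dinucleotide-
preserving shuffle used by the randomisation test is the Altschul-Erikson
Euler-path construction, which keeps the exact dinucleotide composition of
the input so that stacking-energy biases do not inflate significance.
"""

from __future__ import annotations

import random

import RNA

from ._seq import normalize

__all__ = ["fold_rna", "dinucleotide_shuffle", "randfold_pvalue"]

_VALID = frozenset("ACGTU")


def fold_rna(seq: str) -> tuple[str, float]:
    """Minimum-free-energy fold of ``seq``.

    Parameters
    ----------
    seq:
        RNA or DNA string (T and U both accepted), length >= 10.

    Returns
    -------
    (structure, mfe):
        Dot-bracket structure (pseudoknot-free) and MFE in kcal/mol.
        The MFE is <= 0 for any sequence that can pair at all.
    """
    s = seq.upper()
    if not s or set(s) - _VALID:
        bad = sorted(set(s) - _VALID)
        raise ValueError(f"sequence contains non-ACGTU symbols: {bad}")
    if len(s) < 10:
        raise ValueError(f"sequence too short to fold ({len(s)} < 10 nt)")
    structure, mfe = RNA.fold(s.replace("T", "U"))
    return structure, float(mfe)


def pair_table(structure: str) -> list[int]:
    """0-based pairing table: ``pt[i] == j`` iff (i, j) paired, else -1."""
    pt = [-1] * len(structure)
    stack: list[int] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            j = stack.pop()
            pt[i] = j
            pt[j] = i
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return pt


def dinucleotide_shuffle(seq: str, rng: random.Random) -> str:
    """Shuffle ``seq`` preserving its exact dinucleotide composition.

    Altschul-Erikson construction: treat the sequence as an Euler path in
    the multigraph whose vertices are nucleotides and whose edges are the
    observed dinucleotides; sample a uniform random Euler path with the same
    start and end vertex.
    """
    s = normalize(seq)
    if len(s) < 4:
        raise ValueError("sequence too short to shuffle (< 4 nt)")
    if len(set(s)) == 1:
        return s
    edges: dict[str, list[str]] = {}
    for a, b in zip(s, s[1:]):
        edges.setdefault(a, []).append(b)
    last = s[-1]
    vertices = sorted(edges)

    # Pick a random "last edge" for every vertex except the terminal one so
    # that the chosen last edges form a tree directed toward the terminal
    # vertex (the classic connectivity condition for an Euler path).
    while True:
        last_edge: dict[str, str] = {}
        for v in vertices:
            if v != last:
                last_edge[v] = rng.choice(edges[v])
        ok = True
        for v in last_edge:
            seen = {v}
            cur = v
            while cur != last:
                cur = last_edge.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break

    shuffled: dict[str, list[str]] = {}
    for v in vertices:
        pool = list(edges[v])
        if v in last_edge:
            pool.remove(last_edge[v])
        rng.shuffle(pool)
        if v in last_edge:
            pool.append(last_edge[v])
        shuffled[v] = pool

    out = [s[0]]
    cursors = {v: 0 for v in vertices}
    cur = s[0]
    for _ in range(len(s) - 1):
        nxt = shuffled[cur][cursors[cur]]
        cursors[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def randfold_pvalue(precursor: str, n_shuffles: int = 99, seed: int = 0) -> float:
    """Randomisation p-value for the folding stability of a precursor.

    ``p = (1 + #{shuffles with MFE <= observed}) / (1 + n_shuffles)`` over
    dinucleotide-preserving shuffles; a genuine hairpin precursor folds more
    stably than almost all of its shuffles. Candidates pass at p <= 0.1.
    """
    if n_shuffles < 19:
        raise ValueError("n_shuffles must be >= 19 for a usable resolution")
    s = normalize(precursor)
    if len(s) < 4:
        raise ValueError("sequence too short to shuffle (< 4 nt)")
    _, mfe_obs = fold_rna(s)
    rng = random.Random(seed)
    hits = 0
    for _ in range(n_shuffles):
        shuf = dinucleotide_shuffle(s, rng)
        _, mfe = fold_rna(shuf)
        if mfe <= mfe_obs:
            hits += 1
    return (1 + hits) / (1 + n_shuffles)
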