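"""miRNA target support: canonical seed-site scanning and duplex MFE.

Two independent lines of evidence are computed for each candidate
miRNA-target pair:

* presence of a canonical seed-match site on the target read 5'->3'
  (8mer, 7mer-m8, 7mer-A1 or 6mer; seed = miRNA nucleotides 2-7, position
  1 being the miRNA 5' end; the 7mer-A1/8mer "A" is required in the target
  opposite position 1 regardless of the miRNA base), and
* the minimum free energy (mfe, kcal/mol) of the intermolecular
  RNA:RNA duplex, computed by dynamic programming over a
  nearest-neighbor stacking model with affine bulge/internal-loop
  penalties and a duplex-initiation term. Intramolecular structure is not
  modeled; only Watson-Crick and G:U pairs are allowed.

A pair is called a confirmed target when it has at least one seed site
and mfe below a threshold (default -20 kcal/mol).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .seq import complement_rna, to_rna

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")

_WC = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}
_GU = {("G", "U"), ("U", "G")}
_PAIRS = _WC | _GU

_RC_BASE = {"A": "U", "U": "A", "C": "G", "G": "C", "N": "N"}


@dataclass(frozen=True)
class SeedSite:
    mirna_id: str
    target_id: str
    site_type: str  # one of SITE_TYPES
    start: int  # 0-based position of site_sequence on the target (5'->3')
    site_sequence: str


@dataclass
class DuplexResult:
    mirna_id: str
    target_id: str
    mfe: float  # kcal/mol, <= 0 (0 means no stabilizing duplex)
    pairs: List[Tuple[int, int]]  # (miRNA index, target index), 0-based
    structure: Tuple[str, str]  # dot-bracket for (miRNA, target)
    target_window: Tuple[int, int]  # half-open, 0-based


# ---------------------------------------------------------------------------
# energy model
# ---------------------------------------------------------------------------

# Watson-Crick nearest-neighbor stack free energies (kcal/mol, 37 C).
# Key (p, q): p is the 5'-side pair on the miRNA strand, written as
# (miRNA base + target base); q is the next pair toward the miRNA 3' end.
# Values follow the standard RNA nearest-neighbor scale.
_WC_STACKS = {
    ("AU", "AU"): -0.93,
    ("AU", "UA"): -1.10,
    ("UA", "AU"): -1.33,
    ("CG", "AU"): -2.11,
    ("CG", "UA"): -2.08,
    ("GC", "AU"): -2.35,
    ("GC", "UA"): -2.24,
    ("CG", "GC"): -2.36,
    ("GC", "CG"): -3.42,
    ("GC", "GC"): -3.26,
}


def _expand_symmetric(table: Dict[Tuple[str, str], float]) -> Dict[Tuple[str, str], float]:
    out = dict(table)
    for (p, q), v in table.items():
        out.setdefault((q[::-1], p[::-1]), v)
    return out


@dataclass
class EnergyParameters:
    """Simplified duplex energy set.

    ``stack_energy`` covers all Watson-Crick stacks; stacks touching a G:U
    pair fall back to ``gu_stack`` (a single representative value). Bulges
    and internal loops cost an affine penalty in their length; a duplex
    pays ``duplex_init`` once. Loops are capped at ``max_loop`` unpaired
    bases per side.
    """

    stack_energy: Dict[Tuple[str, str], float] = field(
        default_factory=lambda: _expand_symmetric(_WC_STACKS)
    )
    gu_stack: float = -1.25
    bulge_open: float = 3.8
    bulge_ext: float = 0.45
    iloop_open: float = 4.0
    iloop_ext: float = 0.35
    duplex_init: float = 4.1
    max_loop: int = 15

    def stack(self, p: str, q: str) -> float:
        if p in _GU_PAIR_STRINGS or q in _GU_PAIR_STRINGS:
            return self.gu_stack
        return self.stack_energy[(p, q)]

    def bulge(self, length: int) -> float:
        return self.bulge_open + self.bulge_ext * (length - 1)

    def internal_loop(self, length: int) -> float:
        return self.iloop_open + self.iloop_ext * max(length - 2, 0)

    def loop_cost(self, gap_mir: int, gap_target: int) -> float:
        """Penalty for (gap_mir, gap_target) unpaired bases between two
        consecutive pairs; (0, 0) is a stack and not handled here."""
        if gap_mir == 0 and gap_target == 0:
            raise ValueError("(0,0) is a stack, not a loop")
        if gap_mir > self.max_loop or gap_target > self.max_loop:
            return float("inf")
        if gap_mir == 0 or gap_target == 0:
            return self.bulge(gap_mir + gap_target)
        return self.internal_loop(gap_mir + gap_target)

    # -- serialization -----------------------------------------------------

    def to_tsv(self, path) -> None:
        rows = [
            {"pair_5p": p, "pair_3p": q, "energy": v}
            for (p, q), v in sorted(self.stack_energy.items())
        ]
        scalars = {
            "gu_stack": self.gu_stack,
            "bulge_open": self.bulge_open,
            "bulge_ext": self.bulge_ext,
            "iloop_open": self.iloop_open,
            "iloop_ext": self.iloop_ext,
            "duplex_init": self.duplex_init,
            "max_loop": self.max_loop,
        }
        rows += [{"pair_5p": k, "pair_3p": "", "energy": v} for k, v in scalars.items()]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "EnergyParameters":
        df = pd.read_csv(Path(path), sep="\t", keep_default_na=False)
        stacks = {}
        scalars = {}
        for _, row in df.iterrows():
            if row["pair_3p"]:
                stacks[(row["pair_5p"], row["pair_3p"])] = float(row["energy"])
            else:
                scalars[row["pair_5p"]] = float(row["energy"])
        params = cls(stack_energy=stacks)
        for k, v in scalars.items():
            setattr(params, k, int(v) if k == "max_loop" else v)
        return params


_GU_PAIR_STRINGS = {"GU", "UG"}


def default_parameters() -> EnergyParameters:
    return EnergyParameters()


# ---------------------------------------------------------------------------
# seed-site scanning
# ---------------------------------------------------------------------------


def scan_seed_sites(
    mirnas: Dict[str, str], targets: Dict[str, str]
) -> List[SeedSite]:
    """Enumerate all canonical seed sites of every miRNA on every target.

    Each occurrence of the 6-nt seed match is reported exactly once, under
    its most specific type (8mer > 7mer-m8 > 7mer-A1 > 6mer).
    """
    sites: List[SeedSite] = []
    for mid, mseq in mirnas.items():
        mseq = to_rna(mseq)
        if len(mseq) < 8:
            raise ValueError(f"miRNA {mid!r} shorter than 8 nt")
        core = _revcomp6(mseq[1:7])  # target-strand match to seed nt 2-7
        m8_char = _RC_BASE[mseq[7]]  # target base pairing miRNA nt 8
        for tid, tseq in targets.items():
            tseq = to_rna(tseq)
            start = 0
            while True:
                pos = tseq.find(core, start)
                if pos < 0:
                    break
                start = pos + 1
                has_m8 = pos >= 1 and tseq[pos - 1] == m8_char
                has_a1 = pos + 6 < len(tseq) and tseq[pos + 6] == "A"
                if has_m8 and has_a1:
                    site = SeedSite(mid, tid, "8mer", pos - 1, tseq[pos - 1 : pos + 7])
                elif has_m8:
                    site = SeedSite(mid, tid, "7mer-m8", pos - 1, tseq[pos - 1 : pos + 6])
                elif has_a1:
                    site = SeedSite(mid, tid, "7mer-A1", pos, tseq[pos : pos + 7])
                else:
                    site = SeedSite(mid, tid, "6mer", pos, tseq[pos : pos + 6])
                sites.append(site)
    return sites


def _revcomp6(seq: str) -> str:
    return "".join(_RC_BASE[b] for b in reversed(seq))


# ---------------------------------------------------------------------------
# duplex minimum free energy
# ---------------------------------------------------------------------------


def duplex_mfe(
    mirna: str,
    target: str,
    params: Optional[EnergyParameters] = None,
    mirna_id: str = "mirna",
    target_id: str = "target",
) -> DuplexResult:
    """Global minimum-free-energy intermolecular duplex (RNAhybrid-style).

    Dynamic program over (miRNA position, target position): a state is the
    last formed base pair; transitions add a stack, a bulge, or an internal
    loop (each side capped at ``max_loop``). The reported mfe is the global
    minimum over all target windows; if no structure is stabilizing
    (minimum >= 0) the result is mfe = 0 with an empty structure. N is
    unpairable. Ties in the traceback prefer stacking, then the smallest
    loop, then the smaller target index.
    """
    params = params or default_parameters()
    m = to_rna(mirna)
    t = to_rna(target)
    if not m or not t:
        raise ValueError("sequences must be non-empty")
    for name, s in (("miRNA", m), ("target", t)):
        bad = set(s) - set("ACGUN")
        if bad:
            raise ValueError(f"non-RNA characters {sorted(bad)} in {name}")

    # antiparallel pairing: miRNA 5'->3' walks the target 3'->5'
    trev = t[::-1]
    n_m, n_t = len(m), len(t)
    L = params.max_loop

    can_pair = np.zeros((n_m, n_t), dtype=bool)
    for i, a in enumerate(m):
        for k, b in enumerate(trev):
            can_pair[i, k] = (a, b) in _PAIRS

    # penalty grid for (gap_mir, gap_target); (0,0) handled as a stack
    grid = np.full((L + 1, L + 1), np.inf)
    for a in range(L + 1):
        for b in range(L + 1):
            if a == 0 and b == 0:
                continue
            grid[a, b] = params.loop_cost(a, b)

    INF = float("inf")
    E = np.full((n_m, n_t), INF)
    for i in range(n_m):
        for k in range(n_t):
            if not can_pair[i, k]:
                continue
            best = params.duplex_init
            if i >= 1 and k >= 1:
                # stack on the previous pair
                if np.isfinite(E[i - 1, k - 1]) and can_pair[i - 1, k - 1]:
                    cand = E[i - 1, k - 1] + params.stack(
                        m[i - 1] + trev[k - 1], m[i] + trev[k]
                    )
                    if cand < best:
                        best = cand
                # loops: predecessors (i-1-a, k-1-b)
                ia, kb = min(L, i - 1), min(L, k - 1)
                if ia >= 0 and kb >= 0:
                    sub = E[i - 1 - ia : i, k - 1 - kb : k][::-1, ::-1]
                    cand = np.min(sub + grid[: ia + 1, : kb + 1])
                    if cand < best:
                        best = cand
            E[i, k] = best

    if not np.isfinite(E).any() or np.min(E[np.isfinite(E)]) >= 0:
        return DuplexResult(
            mirna_id, target_id, 0.0, [], ("." * n_m, "." * n_t), (0, 0)
        )

    mfe = float(np.min(E[np.isfinite(E)]))
    # last pair of the optimal duplex: scan in (i, k) order so that ties go
    # to the smaller miRNA index, then the smaller reversed-target index
    # (i.e., the 3'-most target window start -> smaller original index gap)
    i, k = map(int, np.argwhere(E == mfe)[0])

    pairs_rev = [(i, k)]
    remaining = mfe
    while True:
        base = E[i, k]
        if abs(base - params.duplex_init) < 1e-9:
            break
        found = False
        # prefer stacking, then smaller loops
        for a in range(0, min(L, i - 1) + 1):
            for b in range(0, min(L, k - 1) + 1):
                pi, pk = i - 1 - a, k - 1 - b
                if pi < 0 or pk < 0 or not np.isfinite(E[pi, pk]):
                    continue
                if a == 0 and b == 0:
                    cost = params.stack(m[pi] + trev[pk], m[i] + trev[k])
                else:
                    cost = grid[a, b]
                if abs(E[pi, pk] + cost - base) < 1e-9:
                    i, k = pi, pk
                    pairs_rev.append((i, k))
                    found = True
                    break
            if found:
                break
        if not found:  # pragma: no cover - defensive
            break

    pairs = [(pi, n_t - 1 - pk) for pi, pk in reversed(pairs_rev)]
    mir_struct = ["."] * n_m
    tgt_struct = ["."] * n_t
    for pi, pj in pairs:
        mir_struct[pi] = "("
        tgt_struct[pj] = ")"
    tgt_positions = [pj for _, pj in pairs]
    window = (min(tgt_positions), max(tgt_positions) + 1)
    return DuplexResult(
        mirna_id,
        target_id,
        round(mfe, 10),
        pairs,
        ("".join(mir_struct), "".join(tgt_struct)),
        window,
    )


# ---------------------------------------------------------------------------
# target calling
# ---------------------------------------------------------------------------


def call_targets(
    sites: Sequence[SeedSite],
    duplexes: Sequence[DuplexResult],
    mfe_threshold: float = -20.0,
) -> List[Tuple[str, str]]:
    """Pairs with at least one seed site and mfe below the threshold."""
    with_site = {(s.mirna_id, s.target_id) for s in sites}
    confirmed = []
    for d in duplexes:
        key = (d.mirna_id, d.target_id)
        if key in with_site and d.mfe < mfe_threshold:
            confirmed.append(key)
    return sorted(set(confirmed))


def sites_to_frame(sites: Sequence[SeedSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mirna_id": s.mirna_id,
                "target_id": s.target_id,
                "site_type": s.site_type,
                "start": s.start,
                "site_sequence": s.site_sequence,
            }
            for s in sites
        ],
        columns=["mirna_id", "target_id", "site_type", "start", "site_sequence"],
    )


def duplexes_to_frame(duplexes: Sequence[DuplexResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mirna_id": d.mirna_id,
                "target_id": d.target_id,
                "mfe": d.mfe,
                "window_start": d.target_window[0],
                "window_end": d.target_window[1],
                "mirna_structure": d.structure[0],
                "target_structure": d.structure[1],
            }
            for d in duplexes
        ],
        columns=[
            "mirna_id",
            "target_id",
            "mfe",
            "window_start",
            "window_end",
            "mirna_structure",
            "target_structure",
        ],
    )
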