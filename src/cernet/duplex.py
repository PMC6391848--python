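"""miRNA–target duplex prediction: seed matching and hybridization MFE.

Implements the canonical targeting rule (perfect Watson–Crick complementarity
of miRNA positions 2–8, the seed) and a minimum-free-energy dynamic program
over *intermolecular-only* secondary structures, in the style of duplex
hybridization tools: the miRNA and a target window hybridize antiparallel,
base pairs are Watson–Crick or G:U, pairs are non-crossing and monotone, and
no intramolecular pairs are allowed.  The energy model is a simplified
nearest-neighbor parameter set shipped as a versioned data file
(``data/nn_energies.json``): stacking free energies, affine bulge/interior
loop penalties and a duplex initiation term.  All energies are in kcal/mol.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")
_COMPLEMENT_WC = {"A": "U", "U": "A", "C": "G", "G": "C"}
# allowed pairs (miRNA base, target base): Watson-Crick plus G:U wobble
_PAIRABLE = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}

SEED_START = 1  # 0-based slice start for miRNA positions 2..8 (1-based)
SEED_END = 8
SEED_LEN = SEED_END - SEED_START


@dataclass(frozen=True)
class SequenceRecord:
    """One RNA sequence with its class label (lncRNA, miRNA or mRNA)."""

    id: str
    rna_class: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.id!r}")
        bad = set(self.sequence) - RNA_ALPHABET
        if bad:
            raise ValueError(
                f"non-RNA characters {sorted(bad)} in sequence {self.id!r}"
            )


@dataclass(frozen=True)
class SeedSite:
    """A perfect seed match on the target, 0-based half-open coordinates."""

    target_start: int
    target_end: int
    mirna_region: tuple[int, int] = (2, 8)  # 1-based miRNA positions, inclusive

    def __post_init__(self) -> None:
        if self.target_end - self.target_start != SEED_LEN:
            raise ValueError("seed site must span exactly 7 nucleotides")


@dataclass
class DuplexResult:
    """Optimal intermolecular hybrid of one miRNA with one target window."""

    mirna_id: str
    target_id: str
    mfe: float  # kcal/mol; 0.0 iff no favorable structure exists
    seed_sites: list[SeedSite] = field(default_factory=list)
    paired_positions: list[tuple[int, int]] = field(default_factory=list)


class EnergyModel:
    """Nearest-neighbor duplex energy parameters loaded from the shipped table."""

    def __init__(self, params: dict):
        self.version = params["version"]
        self.initiation = float(params["initiation"])
        self.bulge_base = float(params["bulge_base"])
        self.bulge_per_nt = float(params["bulge_per_nt"])
        self.interior_base = float(params["interior_base"])
        self.interior_per_nt = float(params["interior_per_nt"])
        self.max_loop = int(params["max_loop_per_side"])
        self._wc = dict(params["stacks_wc"])
        self._one_gu = float(params["stack_one_gu"])
        self._two_gu = float(params["stack_two_gu"])

    @classmethod
    def default(cls) -> "EnergyModel":
        with resources.files("cernet.data").joinpath("nn_energies.json").open() as fh:
            return cls(json.load(fh))

    def stack(self, pair1: str, pair2: str) -> float:
        """Free energy of stacking ``pair2`` on ``pair1``.

        ``pair1``/``pair2`` are two-character strings (miRNA base + target
        base) of consecutive pairs (i, j) and (i+1, j-1).
        """
        gu = sum(p in ("GU", "UG") for p in (pair1, pair2))
        if gu == 0:
            return self._wc[f"{pair1}/{pair2}"]
        return self._one_gu if gu == 1 else self._two_gu

    def loop(self, unpaired_mirna: int, unpaired_target: int) -> float:
        """Affine penalty for a bulge or interior loop between adjacent pairs."""
        total = unpaired_mirna + unpaired_target
        if total == 0:
            raise ValueError("loop requires >=1 unpaired nucleotide")
        if unpaired_mirna > self.max_loop or unpaired_target > self.max_loop:
            return float("inf")
        if unpaired_mirna == 0 or unpaired_target == 0:
            return self.bulge_base + self.bulge_per_nt * total
        return self.interior_base + self.interior_per_nt * total


def _check_rna(seq: str, label: str) -> None:
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise ValueError(f"non-RNA characters {sorted(bad)} in {label}")


def reverse_complement(seq: str) -> str:
    """Watson–Crick reverse complement of an RNA string."""
    _check_rna(seq, "sequence")
    return "".join(_COMPLEMENT_WC[b] for b in reversed(seq))


def read_fasta(path: str | Path, rna_class: str) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords; DNA 'T' is converted to 'U'."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if "T" in seq:
            logger.info("converting T->U in record %s of %s", rec.id, path)
            seq = seq.replace("T", "U")
        records.append(SequenceRecord(id=rec.id, rna_class=rna_class, sequence=seq))
    return records


def seed_match(mirna: SequenceRecord, target: SequenceRecord) -> list[SeedSite]:
    """All perfect seed sites of ``mirna`` on ``target``.

    A site is an occurrence (overlaps included) of the Watson–Crick reverse
    complement of miRNA positions 2–8 (1-based from the 5' end) in the
    target.  G:U wobble is excluded in the seed.
    """
    if len(mirna.sequence) < SEED_END:
        raise ValueError(
            f"miRNA {mirna.id!r} is shorter than 8 nt; seed positions 2-8 undefined"
        )
    site_seq = reverse_complement(mirna.sequence[SEED_START:SEED_END])
    sites = []
    start = target.sequence.find(site_seq)
    while start != -1:
        sites.append(SeedSite(target_start=start, target_end=start + SEED_LEN))
        start = target.sequence.find(site_seq, start + 1)
    return sites


def duplex_mfe(
    mirna: SequenceRecord | str,
    target_window: str,
    model: EnergyModel | None = None,
) -> DuplexResult:
    """Minimum-free-energy intermolecular hybrid of a miRNA with a target window.

    Minimizes over all structures consisting of monotone, non-crossing,
    antiparallel base pairs (Watson–Crick or G:U) between the two strands:

        E = initiation + sum(stack terms) + sum(bulge/interior penalties)

    Consecutive pairs (i, j), (i', j') contribute a stacking term when
    i' = i+1 and j' = j-1, otherwise an affine loop penalty in the number of
    unpaired nucleotides on each strand (each side capped at the model's
    ``max_loop_per_side``).  If no structure has negative energy the result
    is mfe = 0 with an empty pair list.  Among co-optimal structures the
    traceback prefers stacking over loop opening, then smaller target index.
    """
    model = model or _default_model()
    if isinstance(mirna, SequenceRecord):
        mid, mseq = mirna.id, mirna.sequence
    else:
        mid, mseq = "mirna", mirna
    if not mseq or not target_window:
        raise ValueError("both sequences must be non-empty")
    _check_rna(mseq, "miRNA")
    _check_rna(target_window, "target window")

    n, L = len(mseq), len(target_window)
    cap = model.max_loop
    INF = np.inf

    pair_code = np.full((n, L), -1, dtype=np.int64)
    pair_str = {}
    for i, a in enumerate(mseq):
        for j, b in enumerate(target_window):
            if (a, b) in _PAIRABLE:
                pair_code[i, j] = 0
                pair_str[(i, j)] = a + b
    pairable = pair_code == 0

    # affine loop penalty grid over (unpaired on miRNA, unpaired on target);
    # (0, 0) belongs to the stacking transition and is excluded here
    pen = np.full((cap + 1, cap + 1), INF)
    for di in range(cap + 1):
        for dj in range(cap + 1):
            if di == dj == 0:
                continue
            pen[di, dj] = model.loop(di, dj)
    pen_flip = pen[::-1, :]  # rows ordered by ascending predecessor index i'

    E = np.full((n, L), INF)
    for i in range(n):
        row_pair = pairable[i]
        for j in range(L):
            if not row_pair[j]:
                continue
            best = model.initiation  # open a new duplex at (i, j)
            # stacking on the immediately adjacent pair
            if i > 0 and j + 1 < L and np.isfinite(E[i - 1, j + 1]):
                cand = E[i - 1, j + 1] + model.stack(pair_str[(i - 1, j + 1)], pair_str[(i, j)])
                if cand < best:
                    best = cand
            # loop closures from any predecessor within the cap
            i_lo = max(0, i - 1 - cap)
            j_hi = min(L, j + 2 + cap)
            if i > 0 and j + 1 < L:
                window = E[i_lo:i, j + 1:j_hi]
                pslice = pen_flip[cap + 1 - window.shape[0]:, : window.shape[1]]
                cand = np.min(window + pslice) if window.size else INF
                if cand < best:
                    best = cand
            E[i, j] = best

    if not np.isfinite(E).any():
        return DuplexResult(mirna_id=mid, target_id="window", mfe=0.0)
    flat = np.where(np.isfinite(E), E, INF)
    mfe = float(flat.min())
    if mfe >= 0.0:
        return DuplexResult(mirna_id=mid, target_id="window", mfe=0.0)

    # terminal pair: smallest (i, then j) among co-optimal terminals
    ti, tj = map(int, np.argwhere(flat == mfe)[0])
    pairs = _traceback(E, ti, tj, mseq, target_window, pair_str, model, cap)
    return DuplexResult(mirna_id=mid, target_id="window", mfe=mfe, paired_positions=pairs)


def _traceback(E, i, j, mseq, tseq, pair_str, model, cap):
    pairs = [(i, j)]
    n, L = E.shape
    tol = 1e-9
    while abs(E[i, j] - model.initiation) > tol:
        moved = False
        # prefer stacking
        if i > 0 and j + 1 < L and np.isfinite(E[i - 1, j + 1]):
            cand = E[i - 1, j + 1] + model.stack(pair_str[(i - 1, j + 1)], pair_str[(i, j)])
            if abs(cand - E[i, j]) <= tol:
                i, j = i - 1, j + 1
                pairs.append((i, j))
                moved = True
        if not moved:
            # then loops, smaller target index (j') first, then nearer i'
            for jp in range(j + 1, min(L, j + 2 + cap)):
                for ip in range(i - 1, max(-1, i - 2 - cap), -1):
                    if not np.isfinite(E[ip, jp]):
                        continue
                    di, dj = i - ip - 1, jp - j - 1
                    if di == dj == 0:
                        continue
                    if di > cap or dj > cap:
                        continue
                    cand = E[ip, jp] + model.loop(di, dj)
                    if abs(cand - E[i, j]) <= tol:
                        i, j = ip, jp
                        pairs.append((i, j))
                        moved = True
                        break
                if moved:
                    break
        if not moved:  # pragma: no cover - would indicate a DP/traceback mismatch
            raise RuntimeError("traceback failed to find a predecessor")
    pairs.reverse()
    return pairs


_MODEL_CACHE: EnergyModel | None = None


def _default_model() -> EnergyModel:
    global _MODEL_CACHE
    if _MODEL_CACHE is None:
        _MODEL_CACHE = EnergyModel.default()
    return _MODEL_CACHE


def predict_lncrna_targets(
    mirnas: Iterable[SequenceRecord],
    lncrnas: Iterable[SequenceRecord],
    mfe_threshold: float = -20.0,
    window: int = 75,
    model: EnergyModel | None = None,
) -> list[dict]:
    """Predict miRNA–lncRNA interactions by the conjunctive seed + MFE rule.

    A pair is reported iff the lncRNA carries >=1 perfect seed site AND the
    best duplex MFE over windows centered on each seed site is <= the
    threshold (kcal/mol).  A threshold of 0 disables the energy filter, since
    every reported duplex has non-positive energy.

    Returns rows: mirna_id, target_id, mfe, n_seed_sites, best_site_start.
    """
    if mfe_threshold > 0:
        raise ValueError("mfe_threshold must be <= 0 kcal/mol")
    model = model or _default_model()
    half = window // 2
    rows = []
    for mi in mirnas:
        for ln in lncrnas:
            sites = seed_match(mi, ln)
            if not sites:
                continue
            best_mfe, best_start = 0.0, sites[0].target_start
            for site in sites:
                center = site.target_start + SEED_LEN // 2
                lo = max(0, center - half)
                hi = min(len(ln.sequence), center + half + 1)
                res = duplex_mfe(mi, ln.sequence[lo:hi], model=model)
                if res.mfe < best_mfe:
                    best_mfe, best_start = res.mfe, site.target_start
            if best_mfe <= mfe_threshold:
                rows.append(
                    {
                        "mirna_id": mi.id,
                        "target_id": ln.id,
                        "mfe": best_mfe,
                        "n_seed_sites": len(sites),
                        "best_site_start": best_start,
                    }
                )
    logger.info("predicted %d miRNA-lncRNA pairs at MFE <= %.1f kcal/mol",
                len(rows), mfe_threshold)
    return rows
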