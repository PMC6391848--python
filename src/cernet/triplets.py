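"""ceRNA triplet assembly: join database miRNA–mRNA pairs with predicted
miRNA–lncRNA pairs on the shared miRNA."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class InteractionPair:
    """One miRNA–target pair, from the interaction database or predicted."""

    mirna_id: str
    partner_id: str
    partner_class: str  # "lncRNA" or "mRNA"
    source: str  # "database" or "predicted"
    mfe: float | None = None

    def __post_init__(self) -> None:
        if self.partner_class not in ("lncRNA", "mRNA"):
            raise ValueError(f"unknown partner class {self.partner_class!r}")
        if self.source == "predicted" and self.mfe is None:
            raise ValueError("predicted pairs must carry an MFE")
        if self.source == "database" and self.partner_class != "mRNA":
            raise ValueError("database pairs are miRNA-mRNA")


@dataclass(frozen=True, order=True)
class CeRNATriplet:
    """One lncRNA–miRNA–mRNA competing triplet."""

    lncrna_id: str
    mirna_id: str
    mrna_id: str

    def __post_init__(self) -> None:
        if len({self.lncrna_id, self.mirna_id, self.mrna_id}) != 3:
            raise ValueError("triplet members must be distinct")


def load_interaction_db(
    path: str | Path,
    de_mirnas: set[str],
    de_mrnas: set[str],
) -> list[InteractionPair]:
    """Read a 2-column miRNA->mRNA TSV, keeping only differentially expressed ids.

    Duplicate rows collapse to a single pair.
    """
    pairs: set[tuple[str, str]] = set()
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0] or not parts[1]:
                raise ValueError(f"{path}:{lineno}: malformed interaction row {line!r}")
            if parts[0] == "mirna_id":  # header
                continue
            m, g = parts[0], parts[1]
            if m in de_mirnas and g in de_mrnas:
                pairs.add((m, g))
    return [
        InteractionPair(mirna_id=m, partner_id=g, partner_class="mRNA", source="database")
        for m, g in sorted(pairs)
    ]


def build_triplets(
    mirna_lncrna: list[InteractionPair],
    mirna_mrna: list[InteractionPair],
) -> list[CeRNATriplet]:
    """Cartesian join on the shared miRNA; deduplicated and sorted."""
    for p in mirna_lncrna:
        if p.partner_class != "lncRNA":
            raise ValueError(f"expected lncRNA partner, got {p.partner_class} for {p.partner_id}")
    for p in mirna_mrna:
        if p.partner_class != "mRNA":
            raise ValueError(f"expected mRNA partner, got {p.partner_class} for {p.partner_id}")
    lnc_by_mirna: dict[str, set[str]] = {}
    for p in mirna_lncrna:
        lnc_by_mirna.setdefault(p.mirna_id, set()).add(p.partner_id)
    out: set[CeRNATriplet] = set()
    for p in mirna_mrna:
        for ln in lnc_by_mirna.get(p.mirna_id, ()):
            out.add(CeRNATriplet(lncrna_id=ln, mirna_id=p.mirna_id, mrna_id=p.partner_id))
    return sorted(out)


def coexpression_sets(
    triplets: list[CeRNATriplet],
) -> tuple[set[str], set[str], set[str]]:
    """Distinct lncRNA / miRNA / mRNA ids appearing in at least one triplet.

    These are the network's "co-expression" RNAs: co-membership in an
    inferred competing triplet, not expression correlation.
    """
    return (
        {t.lncrna_id for t in triplets},
        {t.mirna_id for t in triplets},
        {t.mrna_id for t in triplets},
    )


def write_triplets(triplets: list[CeRNATriplet], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("lncrna_id\tmirna_id\tmrna_id\n")
        for t in triplets:
            fh.write(f"{t.lncrna_id}\t{t.mirna_id}\t{t.mrna_id}\n")


def read_triplets(path: str | Path) -> list[CeRNATriplet]:
    out = []
    with Path(path).open() as fh:
        header = fh.readline()
        if not header.startswith("lncrna_id"):
            raise ValueError(f"{path}: expected triplet TSV header")
        for line in fh:
            ln, m, g = line.rstrip("\n").split("\t")
            out.append(CeRNATriplet(lncrna_id=ln, mirna_id=m, mrna_id=g))
    return out
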