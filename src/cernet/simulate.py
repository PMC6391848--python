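"""Synthetic data with planted ground truth for the ceRNA inference pipeline.

Emulates the statistical structure of a two-stage (embryo vs adult) bovine
muscle RNA-seq study: three RNA classes, miRNAs mostly down-regulated from
stage1 to stage2 with lncRNAs/mRNAs mostly up, miRNA target sites planted in
lncRNA sequences, a miRNA->mRNA interaction table (a file-based stand-in for
a curated ceRNA-triplet database) and gene-set collections with one set
planted among the up-regulated mRNAs.  Every output is a pure function of
the configuration and its seed.

Counts follow a negative-binomial (gamma-Poisson) model with per-class mean
profiles drawn once per simulation.  Planted up-regulated RNAs reach a
typical expression level in their high stage (and sit ``2^-log2fc`` below it
in the other), so that stage library sizes stay close to each other and the
CPM-scale fold-change estimate is only mildly compressed by composition.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .diffexpr import ExpressionMatrix, write_counts
from .duplex import SEED_END, SequenceRecord, reverse_complement

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGU"))


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic two-stage experiment."""

    n_lncrna: int = 24
    n_mirna: int = 8
    n_mrna: int = 200
    n_replicates_per_stage: int = 6  # six RNA samples per stage in the emulated design
    lncrna_len: int = 400
    mrna_len: int = 500
    mirna_len: int = 22
    de_fraction: dict = field(
        default_factory=lambda: {"lncRNA": 10 / 24, "miRNA": 0.5, "mRNA": 0.08}
    )
    true_log2fc: float = 5.0
    dispersion: float = 0.05
    library_size: float = 1e6
    site_plant_fraction: float = 1.0
    #: planted target-site length on the lncRNA (reverse complement of the
    #: miRNA 5' prefix of this length); None = full miRNA length, so planted
    #: sites pair along the whole miRNA (seed plus 3'-supplementary pairing)
    site_length: int | None = None
    lncrna_partners_per_mirna: int = 2
    mrna_partners_per_mirna: int = 2
    rng_seed: int = 0

    def validate(self) -> None:
        for name in ("n_lncrna", "n_mirna", "n_mrna", "n_replicates_per_stage",
                     "lncrna_len", "mrna_len"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.mirna_len < SEED_END:
            raise ValueError("mirna_len must be >= 8 so seed positions 2-8 exist")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if not 0 <= self.site_plant_fraction <= 1:
            raise ValueError("site_plant_fraction must be in [0, 1]")
        site_len = self.site_length or self.mirna_len
        if site_len > self.lncrna_len:
            raise ValueError("planted site longer than the lncRNA")


PLANTED_SET_NAME = "PLANTED_UP_MRNA_SET"


@dataclass
class GroundTruth:
    """What was planted: triplets, DE effects and the enriched gene set."""

    planted_triplets: list[tuple[str, str, str]]
    planted_de_ids: dict[str, list[tuple[str, float]]]
    planted_enriched_sets: list[str]
    rng_seed: int
    all_ids: dict[str, list[str]] = field(default_factory=dict)

    def de_ids(self, rna_class: str) -> set[str]:
        return {i for i, _ in self.planted_de_ids.get(rna_class, [])}

    def to_json(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        payload["planted_triplets"] = [list(t) for t in self.planted_triplets]
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        d["planted_triplets"] = [tuple(t) for t in d["planted_triplets"]]
        d["planted_de_ids"] = {
            k: [(i, float(f)) for i, f in v] for k, v in d["planted_de_ids"].items()
        }
        return cls(**d)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i + 1:04d}" for i in range(n)]


def generate_sequences(config: SimulationConfig) -> tuple[list[SequenceRecord], GroundTruth]:
    """Emit miRNA/lncRNA/mRNA sequences and the planted ground truth.

    Planted (lncRNA, miRNA) pairs carry the reverse complement of the miRNA
    5' prefix (length ``site_length``) at a random non-overlapping position,
    which in particular contains a perfect seed site (positions 2-8);
    everything else is uniform random RNA.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)

    lnc_ids = _ids("LNC", config.n_lncrna)
    mir_ids = _ids("MIR", config.n_mirna)
    mrna_ids = _ids("GENE", config.n_mrna)
    all_ids = {"lncRNA": lnc_ids, "miRNA": mir_ids, "mRNA": mrna_ids}

    de_ids: dict[str, list[tuple[str, float]]] = {}
    for cls, ids in all_ids.items():
        n_de = int(round(len(ids) * config.de_fraction.get(cls, 0.0)))
        chosen = sorted(rng.choice(ids, size=n_de, replace=False)) if n_de else []
        sign = -1.0 if cls == "miRNA" else 1.0  # miRNAs go down embryo->adult
        de_ids[cls] = [(i, sign * config.true_log2fc) for i in chosen]

    # candidate triplets: each DE miRNA gets a few DE lncRNA and DE mRNA partners
    de_lnc = [i for i, _ in de_ids["lncRNA"]]
    de_mir = [i for i, _ in de_ids["miRNA"]]
    de_mrna = [i for i, _ in de_ids["mRNA"]]
    planted_pairs: list[tuple[str, str]] = []  # (mirna, lncrna) with planted site
    triplets: list[tuple[str, str, str]] = []
    for m in de_mir:
        k_l = min(config.lncrna_partners_per_mirna, len(de_lnc))
        k_g = min(config.mrna_partners_per_mirna, len(de_mrna))
        if k_l == 0 or k_g == 0:
            continue
        lncs = sorted(rng.choice(de_lnc, size=k_l, replace=False))
        genes = sorted(rng.choice(de_mrna, size=k_g, replace=False))
        for ln in lncs:
            if rng.random() <= config.site_plant_fraction:
                planted_pairs.append((m, ln))
                triplets.extend((ln, m, g) for g in genes)
    triplets = sorted(set(triplets))

    mir_seqs = {m: _random_seq(rng, config.mirna_len) for m in mir_ids}

    site_len = config.site_length or config.mirna_len
    lnc_seqs: dict[str, str] = {}
    sites_by_lnc: dict[str, list[str]] = {}
    for m, ln in planted_pairs:
        sites_by_lnc.setdefault(ln, []).append(reverse_complement(mir_seqs[m][:site_len]))
    for ln in lnc_ids:
        seq = list(_random_seq(rng, config.lncrna_len))
        occupied: list[tuple[int, int]] = []
        for site in sites_by_lnc.get(ln, []):
            for _ in range(1000):
                start = int(rng.integers(0, config.lncrna_len - len(site) + 1))
                if all(start + len(site) <= a or start >= b for a, b in occupied):
                    break
            else:  # pragma: no cover - lncRNA essentially full of sites
                raise RuntimeError(f"could not place all sites in {ln}")
            seq[start:start + len(site)] = list(site)
            occupied.append((start, start + len(site)))
        lnc_seqs[ln] = "".join(seq)

    records = (
        [SequenceRecord(i, "miRNA", mir_seqs[i]) for i in mir_ids]
        + [SequenceRecord(i, "lncRNA", lnc_seqs[i]) for i in lnc_ids]
        + [SequenceRecord(i, "mRNA", _random_seq(rng, config.mrna_len)) for i in mrna_ids]
    )
    truth = GroundTruth(
        planted_triplets=triplets,
        planted_de_ids=de_ids,
        planted_enriched_sets=[PLANTED_SET_NAME],
        rng_seed=config.rng_seed,
        all_ids=all_ids,
    )
    return records, truth


def generate_expression(
    config: SimulationConfig,
    truth: GroundTruth,
    noise: str = "nb",
) -> ExpressionMatrix:
    """Negative-binomial counts for both stages with the planted fold changes.

    ``noise="nb"`` draws gamma-Poisson counts at dispersion ``config.dispersion``;
    ``noise="none"`` emits the (rounded) expected counts, a noise-free matrix
    for exact-recovery experiments.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed + 1)  # distinct stream from sequences

    ids, classes, lfc = [], [], []
    planted = {c: dict(v) for c, v in truth.planted_de_ids.items()}
    for cls, class_ids in truth.all_ids.items():
        for i in class_ids:
            ids.append(i)
            classes.append(cls)
            lfc.append(planted.get(cls, {}).get(i, 0.0))
    lfc = np.array(lfc)
    n = len(ids)
    if n == 0:
        raise ValueError("ground truth contains no RNA ids")

    base = rng.lognormal(mean=0.0, sigma=1.0, size=n)
    base *= config.library_size / base.sum()
    # planted RNAs reach a typical level in their high-expression stage
    mean1 = np.where(lfc > 0, base * 2.0 ** -lfc, base)
    mean2 = mean1 * 2.0 ** lfc

    reps = config.n_replicates_per_stage
    samples = [f"E{r + 1}" for r in range(reps)] + [f"A{r + 1}" for r in range(reps)]
    stage_of = {s: ("stage1" if s.startswith("E") else "stage2") for s in samples}

    cols = {}
    for s in samples:
        mu = mean1 if stage_of[s] == "stage1" else mean2
        if noise == "none":
            cols[s] = np.round(mu)
        elif noise == "nb":
            lam = rng.gamma(shape=1.0 / config.dispersion, scale=mu * config.dispersion)
            cols[s] = rng.poisson(lam).astype(float)
        else:
            raise ValueError(f"unknown noise model {noise!r}")
    counts = pd.DataFrame(cols, index=ids)
    return ExpressionMatrix(
        counts=counts,
        classes=pd.Series(classes, index=ids),
        stages=pd.Series(stage_of),
    )


def generate_interaction_db(
    truth: GroundTruth,
    decoy_pairs: int = 15,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """miRNA->mRNA table: the planted triplet pairs plus random decoys.

    Decoys are uniform random (miRNA, mRNA) pairs that are not part of any
    planted triplet, emulating database entries irrelevant to the contrast.
    """
    if decoy_pairs < 0:
        raise ValueError("decoy_pairs must be >= 0")
    rng = np.random.default_rng(rng_seed)
    planted = sorted({(m, g) for _, m, g in truth.planted_triplets})
    taken = set(planted)
    mirnas = truth.all_ids.get("miRNA", [])
    mrnas = truth.all_ids.get("mRNA", [])
    decoys: list[tuple[str, str]] = []
    max_pairs = len(mirnas) * len(mrnas)
    if decoy_pairs > max_pairs - len(taken):
        raise ValueError("more decoys requested than free (miRNA, mRNA) pairs")
    while len(decoys) < decoy_pairs:
        pair = (str(rng.choice(mirnas)), str(rng.choice(mrnas)))
        if pair not in taken:
            taken.add(pair)
            decoys.append(pair)
    rows = planted + sorted(decoys)
    return pd.DataFrame(rows, columns=["mirna_id", "mrna_id"])


def generate_genesets(
    truth: GroundTruth,
    n_sets: int = 20,
    set_size_range: tuple[int, int] = (10, 20),
    rng_seed: int = 0,
    planted_purity: float = 0.9,
) -> dict[str, tuple[str, list[str]]]:
    """Gene sets over the mRNA universe; one set planted in the up-regulated mRNAs.

    The planted set draws a fraction ``planted_purity`` (>= 0.8) of its
    members from the planted up-regulated mRNAs; all other sets are uniform
    draws from the universe.  Returns {name: (description, members)}.
    """
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    if planted_purity < 0.8:
        raise ValueError("planted set must be drawn predominantly (>=0.8) from planted mRNAs")
    rng = np.random.default_rng(rng_seed)
    universe = list(truth.all_ids.get("mRNA", []))
    lo, hi = set_size_range
    if hi > len(universe):
        raise ValueError("set size exceeds the mRNA universe")

    up = sorted(i for i, f in truth.planted_de_ids.get("mRNA", []) if f > 0)
    sets: dict[str, tuple[str, list[str]]] = {}

    size = int(rng.integers(lo, hi + 1))
    if up:
        # cap so the planted fraction stays >= planted_purity even when the
        # pool of up-regulated mRNAs is small
        size = min(size, max(1, int(len(up) / planted_purity)))
    n_planted = min(int(np.ceil(size * planted_purity)), len(up))
    members = sorted(rng.choice(up, size=n_planted, replace=False))
    others = [g for g in universe if g not in members]
    n_fill = min(size - n_planted, len(others))
    if n_fill:
        members += sorted(rng.choice(others, size=n_fill, replace=False))
    sets[PLANTED_SET_NAME] = (f"planted up-regulated set (rng_seed={rng_seed})", members)

    for k in range(n_sets - 1):
        size = int(rng.integers(lo, hi + 1))
        members = sorted(rng.choice(universe, size=size, replace=False))
        sets[f"RANDOM_SET_{k + 1:03d}"] = (f"random set (rng_seed={rng_seed})", members)
    return sets


def write_gmt(sets: dict[str, tuple[str, list[str]]], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for name, (desc, members) in sets.items():
            fh.write("\t".join([name, desc] + list(members)) + "\n")


def write_fasta(records: list[SequenceRecord], path: str | Path, seed: int | None = None) -> None:
    with Path(path).open("w") as fh:
        for rec in records:
            desc = f" class={rec.rna_class}" + (f" rng_seed={seed}" if seed is not None else "")
            fh.write(f">{rec.id}{desc}\n{rec.sequence}\n")


def simulate_bundle(config: SimulationConfig, outdir: str | Path, decoy_pairs: int = 15,
                    n_sets: int = 20, noise: str = "nb") -> GroundTruth:
    """Write the full synthetic input bundle for a pipeline run."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, truth = generate_sequences(config)
    by_class: dict[str, list[SequenceRecord]] = {}
    for r in records:
        by_class.setdefault(r.rna_class, []).append(r)
    for cls, fname in (("miRNA", "mirna.fasta"), ("lncRNA", "lncrna.fasta"), ("mRNA", "mrna.fasta")):
        write_fasta(by_class.get(cls, []), outdir / fname, seed=config.rng_seed)
    matrix = generate_expression(config, truth, noise=noise)
    write_counts(matrix, outdir / "counts.tsv", seed=config.rng_seed)
    db = generate_interaction_db(truth, decoy_pairs=decoy_pairs, rng_seed=config.rng_seed)
    db.to_csv(outdir / "interactions.tsv", sep="\t", index=False)
    write_gmt(generate_genesets(truth, n_sets=n_sets, rng_seed=config.rng_seed),
              outdir / "genesets.gmt")
    truth.to_json(outdir / "truth.json")
    logger.info("synthetic bundle written to %s (seed=%d, %d planted triplets)",
                outdir, config.rng_seed, len(truth.planted_triplets))
    return truth
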