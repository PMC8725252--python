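"""Synthetic multi-omic data with planted, machine-readable ground truth.

The generator emulates the statistical structure the ceRNA pipeline's
filters assume, without modelling titration mechanism:

* a two-condition design (induced vs control, ``n_per_condition`` each);
* planted triplets per stratum: a shared Gaussian latent factor per
  triplet plus a condition mean shift of ``de_effect`` log2 units drive
  the lncRNA and mRNA together and the miRNA oppositely, so pooled
  lncRNA-mRNA correlation is strongly positive and both miRNA-target
  correlations strongly negative;  ``triplet_coupling`` is the fraction
  of each planted feature's within-condition variance carried by the
  shared factor, so the total per-feature variance stays at
  ``noise_sd**2`` regardless of the coupling;
* background features: condition-free Gaussian noise around a baseline;
* sequences: each planted binding site is the exact reverse complement
  of its miRNA spliced into an otherwise random target at a recorded
  1-based position; decoy targets are rejection-sampled to contain no
  8-nt-or-longer exact complement to any miRNA;
* gene sets: one term packed with planted-up mRNAs plus uniformly
  sampled background terms.

With the default coupling (0.8) the population pooled correlation of a
planted lncRNA-mRNA pair is (de^2/4 + c*sd^2) / (de^2/4 + sd^2)
~= 0.981, so sample correlations at n = 12 clear the r > 0.90 filter
with high probability while the differential screen keeps its full
power (within-condition sd stays at ``noise_sd``).  Planted miRNAs are additionally rejection-
sampled so their perfect-duplex nearest-neighbour energy sits below
-35 kcal/mol, emulating the GC content of real miRNAs and keeping the
planted sites recoverable under the -30 kcal/mol ceiling.

Everything is deterministic given the config seed; the three stages
draw from independently derived streams.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from cernet.core_io import ExpressionBundle, GeneSet, GeneSetCollection, SampleSheet, write_expression, write_gmt
from cernet.errors import ValidationError
from cernet.targets import RNA_BASES, perfect_duplex_energy, reverse_complement, write_fasta

MIN_COMPLEMENT_FREE = 8  # decoys carry no exact complement of this length or longer


@dataclass(frozen=True)
class SimulationConfig:
    """Study design of the synthetic experiment (all units log2 where expressional)."""

    n_per_condition: int = 6
    n_background_lncrna: int = 200
    n_background_mirna: int = 60
    n_background_mrna: int = 300
    n_planted_triplets: int = 40  # per stratum
    de_effect: float = 2.5
    noise_sd: float = 0.4
    triplet_coupling: float = 0.8
    baseline_range: tuple[float, float] = (6.0, 10.0)
    seq_length_target: int = 500
    mirna_length: int = 22
    n_decoy_targets: int = 60
    sites_per_target: int = 1
    mirna_energy_margin: float = -35.0
    enriched_term_size: int = 10
    enriched_overlap: float = 0.8
    n_background_terms: int = 30
    background_term_size: tuple[int, int] = (10, 50)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_condition < 3:
            raise ValidationError("n_per_condition must be >= 3")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        for name in ("n_background_lncrna", "n_background_mirna", "n_background_mrna",
                     "seq_length_target", "mirna_length"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.n_planted_triplets < 0 or self.n_decoy_targets < 0:
            raise ValidationError("counts must be non-negative")
        if not 0.0 <= self.enriched_overlap <= 1.0:
            raise ValidationError("enriched_overlap must be in [0, 1]")
        if not 0.0 <= self.triplet_coupling <= 1.0:
            raise ValidationError("triplet_coupling is a variance fraction in [0, 1]")
        if self.seq_length_target < self.mirna_length * self.sites_per_target * 2:
            raise ValidationError("target length too short for the requested planted sites")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stream])


@dataclass(frozen=True)
class PlantedTriplet:
    lncrna_id: str
    mirna_id: str
    mrna_id: str
    stratum: str

    def key(self) -> tuple[str, str, str]:
        return (self.lncrna_id, self.mirna_id, self.mrna_id)


@dataclass(frozen=True)
class PlantedSite:
    mirna_id: str
    target_id: str
    target_class: str
    start: int  # 1-based inclusive
    end: int


@dataclass
class GroundTruth:
    """Planted truth emitted by the simulator, the oracle for recovery tests."""

    de_directions: dict[str, dict[str, str]] = field(
        default_factory=lambda: {"lncRNA": {}, "miRNA": {}, "mRNA": {}})
    triplets: list[PlantedTriplet] = field(default_factory=list)
    sites: list[PlantedSite] = field(default_factory=list)
    enriched_terms: dict[str, list[str]] = field(default_factory=dict)

    def triplet_keys(self) -> set[tuple[str, str, str]]:
        return {t.key() for t in self.triplets}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "de_directions": self.de_directions,
            "triplets": [asdict(t) for t in self.triplets],
            "sites": [asdict(s) for s in self.sites],
            "enriched_terms": self.enriched_terms,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            de_directions=payload["de_directions"],
            triplets=[PlantedTriplet(**t) for t in payload["triplets"]],
            sites=[PlantedSite(**s) for s in payload["sites"]],
            enriched_terms=payload["enriched_terms"],
        )


_STRATUM_TAG = {"UP": "U", "DOWN": "D"}
_STRATUM_SIGN = {"UP": 1.0, "DOWN": -1.0}


def _planted_ids(stratum: str, i: int) -> tuple[str, str, str]:
    tag = _STRATUM_TAG[stratum]
    return (f"LNC_{tag}{i:03d}", f"MIR_{tag}{i:03d}", f"MRNA_{tag}{i:03d}")


def simulate_expression(config: SimulationConfig) -> tuple[ExpressionBundle, GroundTruth]:
    """Generate the three-class expression bundle with planted triplets."""
    rng = config.rng(0)
    n = config.n_per_condition
    samples = tuple(f"IND_{i+1:02d}" for i in range(n)) + tuple(f"CTL_{i+1:02d}" for i in range(n))
    conditions = ("induced",) * n + ("control",) * n
    sheet = SampleSheet(samples, conditions)
    cvec = np.array([0.5] * n + [-0.5] * n)  # centred condition indicator

    truth = GroundTruth()
    rows: dict[str, list[tuple[str, np.ndarray]]] = {"lncRNA": [], "miRNA": [], "mRNA": []}
    lo, hi = config.baseline_range

    def noise() -> np.ndarray:
        return rng.normal(0.0, config.noise_sd, size=2 * n)

    shared_sd = config.noise_sd * np.sqrt(config.triplet_coupling)
    resid_sd = config.noise_sd * np.sqrt(1.0 - config.triplet_coupling)

    def resid() -> np.ndarray:
        return rng.normal(0.0, resid_sd, size=2 * n) if resid_sd > 0 else np.zeros(2 * n)

    for stratum in ("UP", "DOWN"):
        sign = _STRATUM_SIGN[stratum]
        for i in range(config.n_planted_triplets):
            lnc, mir, mrna = _planted_ids(stratum, i + 1)
            z = rng.normal(0.0, 1.0, size=2 * n)
            signal = sign * config.de_effect * cvec + shared_sd * z
            bases = rng.uniform(lo, hi, size=3)
            rows["lncRNA"].append((lnc, bases[0] + signal + resid()))
            rows["mRNA"].append((mrna, bases[1] + signal + resid()))
            rows["miRNA"].append((mir, bases[2] - signal + resid()))
            target_dir = "up" if stratum == "UP" else "down"
            mir_dir = "down" if stratum == "UP" else "up"
            truth.de_directions["lncRNA"][lnc] = target_dir
            truth.de_directions["mRNA"][mrna] = target_dir
            truth.de_directions["miRNA"][mir] = mir_dir
            truth.triplets.append(PlantedTriplet(lnc, mir, mrna, stratum))

    for cls, count, prefix in (("lncRNA", config.n_background_lncrna, "LNC_BG"),
                               ("miRNA", config.n_background_mirna, "MIR_BG"),
                               ("mRNA", config.n_background_mrna, "MRNA_BG")):
        for i in range(count):
            base = rng.uniform(lo, hi)
            rows[cls].append((f"{prefix}{i+1:04d}", base + noise()))

    frames = {
        cls: pd.DataFrame([v for _, v in pairs], index=[k for k, _ in pairs],
                          columns=list(samples))
        for cls, pairs in rows.items()
    }
    bundle = ExpressionBundle(lncrna=frames["lncRNA"], mirna=frames["miRNA"],
                              mrna=frames["mRNA"], sheet=sheet)
    truth.triplets.sort(key=PlantedTriplet.key)
    return bundle, truth


def _random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(RNA_BASES), size=length))


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def _complement_kmers(mirna_seqs: dict[str, str], k: int) -> dict[str, set[str]]:
    """For each miRNA, the k-mers a target would need to complement it."""
    out = {}
    for mid, seq in mirna_seqs.items():
        rc = reverse_complement(seq)
        out[mid] = _kmers(rc, k)
    return out


def _clean_of_complements(seq: str, banned: set[str]) -> bool:
    return not (_kmers(seq, MIN_COMPLEMENT_FREE) & banned)


def _scrub(seq: str, banned: set[str], rng: np.random.Generator,
           protected: list[tuple[int, int]] | None = None, max_rounds: int = 200) -> str:
    """Remove banned k-mers by mutating a base inside each occurrence.

    ``protected`` lists 0-based half-open intervals that must not be
    touched (planted sites).  A banned k-mer lying entirely inside a
    protected interval is left alone (it cannot be removed without
    destroying the planted site, and an isolated 8-mer cannot pass the
    score/energy thresholds anyway).
    """
    k = MIN_COMPLEMENT_FREE
    protected = protected or []
    chars = list(seq)

    def editable(pos: int) -> bool:
        return all(not (a <= pos < b) for a, b in protected)

    for _ in range(max_rounds):
        dirty = [i for i in range(len(chars) - k + 1)
                 if "".join(chars[i:i + k]) in banned]
        fixable = False
        for i in dirty:
            spots = [p for p in range(i, i + k) if editable(p)]
            if not spots:
                continue
            p = spots[len(spots) // 2]
            alternatives = [b for b in RNA_BASES if b != chars[p]]
            chars[p] = alternatives[int(rng.integers(0, 3))]
            fixable = True
        if not dirty or not fixable:
            break
    return "".join(chars)


def simulate_sequences(
    config: SimulationConfig,
    truth: GroundTruth | None = None,
) -> tuple[dict[str, str], dict[str, str], GroundTruth]:
    """Generate miRNA and target sequences with planted binding sites.

    Returns (miRNA id->seq, target id->seq, truth).  When an expression
    ``truth`` is supplied its planted ids are reused so the sequence and
    expression layers describe the same molecules, and the planted-site
    records are appended to it; otherwise a fresh truth is created.

    Every planted site is the exact reverse complement of its miRNA at
    a recorded 1-based position; decoy targets contain no exact
    complement of length >= 8 to any miRNA.
    """
    rng = config.rng(1)
    if truth is None:
        truth = GroundTruth()
        for stratum in ("UP", "DOWN"):
            for i in range(config.n_planted_triplets):
                truth.triplets.append(PlantedTriplet(*_planted_ids(stratum, i + 1), stratum))

    # planted miRNAs: rejection-sampled for a stable perfect duplex
    mirna_seqs: dict[str, str] = {}
    for t in sorted(truth.triplets, key=PlantedTriplet.key):
        if t.mirna_id in mirna_seqs:
            continue
        for _ in range(10_000):
            cand = _random_rna(rng, config.mirna_length)
            if perfect_duplex_energy(cand) <= config.mirna_energy_margin:
                mirna_seqs[t.mirna_id] = cand
                break
        else:  # pragma: no cover
            raise ValidationError("could not sample a sufficiently stable miRNA sequence")

    banned = _complement_kmers(mirna_seqs, MIN_COMPLEMENT_FREE)
    all_banned: set[str] = set().union(*banned.values()) if banned else set()

    target_seqs: dict[str, str] = {}
    L = config.mirna_length

    def plant(target_id: str, target_class: str, mirna_id: str) -> None:
        site_seq = reverse_complement(mirna_seqs[mirna_id])
        other_banned = all_banned - banned[mirna_id]
        backbone = _scrub(_random_rna(rng, config.seq_length_target), all_banned, rng)
        # choose non-overlapping positions for the requested site count
        positions: list[int] = []
        for _ in range(config.sites_per_target):
            for _ in range(10_000):
                pos = int(rng.integers(0, config.seq_length_target - L + 1))
                if all(pos + L <= p or pos >= p + L for p in positions):
                    positions.append(pos)
                    break
            else:  # pragma: no cover
                raise ValidationError(f"could not place non-overlapping sites in {target_id}")
        seq = backbone
        for pos in positions:
            seq = seq[:pos] + site_seq + seq[pos + L:]
        # splice junctions may accidentally complement another miRNA
        seq = _scrub(seq, other_banned, rng,
                     protected=[(p, p + L) for p in positions])
        target_seqs[target_id] = seq
        for pos in sorted(positions):
            truth.sites.append(PlantedSite(mirna_id, target_id, target_class,
                                           pos + 1, pos + L))

    for t in sorted(truth.triplets, key=PlantedTriplet.key):
        plant(t.lncrna_id, "lncRNA", t.mirna_id)
        plant(t.mrna_id, "mRNA", t.mirna_id)

    for i in range(config.n_decoy_targets):
        cand = _scrub(_random_rna(rng, config.seq_length_target), all_banned, rng)
        target_seqs[f"DECOY_{i+1:04d}"] = cand

    return mirna_seqs, target_seqs, truth


def simulate_genesets(config: SimulationConfig, truth: GroundTruth) -> GeneSetCollection:
    """Gene-set collection with one term packed with planted-up mRNAs.

    The universe is every mRNA id in the expression layer (planted plus
    background); the enriched term draws ``enriched_overlap`` of its
    members from the planted-up mRNAs and the rest from the remainder,
    and background terms are uniform draws from the whole universe.
    """
    rng = config.rng(2)
    planted_up = sorted(fid for fid, d in truth.de_directions["mRNA"].items() if d == "up")
    if not planted_up:
        raise ValidationError("simulate_genesets requires planted DE mRNAs in the truth")
    background = [f"MRNA_BG{i+1:04d}" for i in range(config.n_background_mrna)]
    universe = sorted(set(truth.de_directions["mRNA"]) | set(background))
    if config.enriched_term_size > len(universe):
        raise ValidationError("enriched term size exceeds the mRNA universe")
    hi = min(config.background_term_size[1], len(universe))
    lo = min(config.background_term_size[0], hi)

    n_overlap = int(round(config.enriched_overlap * config.enriched_term_size))
    n_overlap = min(n_overlap, len(planted_up), config.enriched_term_size)
    members = list(rng.choice(planted_up, size=n_overlap, replace=False))
    rest_pool = sorted(set(universe) - set(planted_up))
    members += list(rng.choice(rest_pool, size=config.enriched_term_size - n_overlap, replace=False))
    terms = [GeneSet("SYN:ENRICHED", "planted enriched process", frozenset(members), "GO-BP")]
    truth.enriched_terms["SYN:ENRICHED"] = sorted(set(members) & set(planted_up))

    for i in range(config.n_background_terms):
        size = int(rng.integers(lo, hi + 1))
        bg = rng.choice(universe, size=size, replace=False)
        terms.append(GeneSet(f"SYN:BG{i+1:04d}", f"background set {i+1}", frozenset(bg), "GO-BP"))
    return GeneSetCollection(terms)


def write_simulation(config: SimulationConfig, directory: str | Path) -> dict[str, Path]:
    """Run all three generators and write every artifact core_io can read back."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    bundle, truth = simulate_expression(config)
    mirnas, targets, truth = simulate_sequences(config, truth)
    collection = simulate_genesets(config, truth)
    paths = write_expression(bundle, directory)
    write_fasta(mirnas, directory / "mirna.fasta")
    write_fasta(targets, directory / "targets.fasta")
    write_gmt(collection, directory / "genesets.gmt")
    truth.to_json(directory / "truth.json")
    paths.update({"mirna_fasta": directory / "mirna.fasta",
                  "target_fasta": directory / "targets.fasta",
                  "gmt": directory / "genesets.gmt",
                  "truth": directory / "truth.json"})
    return paths
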