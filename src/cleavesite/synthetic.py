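"""Seeded synthetic data: proteins, rule-based cleavage, structure, digests.

Every downstream stage of the pipeline (encoding, model training,
evaluation, susceptibility scoring) can be exercised against data whose
ground truth is an explicit cleavage rule, e.g. the trypsin specificity
"C-terminal side of Arg and Lys, unless followed by Pro".  In the
noise-free limit (``site_probability=1``, ``decoy_rate=0``) the emitted
annotations equal the deterministic rule enumeration exactly, giving an
oracle for the learned models.

All randomness flows from explicit integer seeds; repeated generation with
the same seeds is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d

from .core import (
    STANDARD_AA,
    AnnotationSource,
    CleavageAnnotation,
    PeptideHit,
    ProteaseRegistry,
    ProteinRecord,
    StructuralFeatures,
    ValidationError,
    write_cleavage_table,
    write_disulfide_table,
    write_fasta,
)


@dataclass(frozen=True)
class CleavageRule:
    """A positional protease specificity rule with optional noise.

    A candidate bond (P1 at position ``p1``) is *licensed* when the P1
    residue is in ``p1_residues`` (or ``p1_overrides``) and the P1' residue
    is not in ``blocked_p1prime``.  Licensed sites are emitted with
    probability ``site_probability`` (``p1_overrides`` maps individual P1
    letters to their own emission probability, used to express
    preferences such as GluC's Glu >> Asp); non-licensed candidates are
    emitted spuriously with probability ``decoy_rate``.
    """

    name: str
    p1_residues: frozenset[str]
    blocked_p1prime: frozenset[str] = frozenset()
    site_probability: float = 1.0
    decoy_rate: float = 0.0
    p1_overrides: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "p1_residues", frozenset(self.p1_residues))
        object.__setattr__(self, "blocked_p1prime", frozenset(self.blocked_p1prime))
        object.__setattr__(self, "p1_overrides", tuple(self.p1_overrides))
        if not self.p1_residues and not self.p1_overrides:
            raise ValidationError(f"rule {self.name}: p1_residues must be non-empty")
        if not (0.0 < self.site_probability <= 1.0):
            raise ValidationError(f"rule {self.name}: site_probability outside (0, 1]")
        if not (0.0 <= self.decoy_rate < 1.0):
            raise ValidationError(f"rule {self.name}: decoy_rate outside [0, 1)")

    def emission_probability(self, p1_aa: str, p1prime_aa: str | None) -> float:
        """Probability that the bond after ``p1_aa`` is emitted as a site."""
        if p1prime_aa is not None and p1prime_aa in self.blocked_p1prime:
            return self.decoy_rate
        for aa, prob in self.p1_overrides:
            if aa == p1_aa:
                return prob
        if p1_aa in self.p1_residues:
            return self.site_probability
        return self.decoy_rate

    def is_licensed(self, p1_aa: str, p1prime_aa: str | None) -> bool:
        if p1prime_aa is not None and p1prime_aa in self.blocked_p1prime:
            return False
        return p1_aa in self.p1_residues or any(aa == p1_aa for aa, _ in self.p1_overrides)


def trypsin_rule(site_probability: float = 1.0, decoy_rate: float = 0.0) -> CleavageRule:
    """Trypsin: cleave after Lys/Arg unless the next residue is Pro."""
    return CleavageRule(
        name="trypsin",
        p1_residues=frozenset("KR"),
        blocked_p1prime=frozenset("P"),
        site_probability=site_probability,
        decoy_rate=decoy_rate,
    )


def gluc_rule(
    glu_probability: float = 1.0, asp_probability: float = 0.2, decoy_rate: float = 0.0
) -> CleavageRule:
    """V8/GluC: cleave after Glu, with a weaker preference for Asp."""
    return CleavageRule(
        name="gluc",
        p1_residues=frozenset("E"),
        site_probability=glu_probability,
        decoy_rate=decoy_rate,
        p1_overrides=(("D", asp_probability),),
    )


@dataclass(frozen=True)
class StructureParams:
    """Knobs for the structural-feature simulator.

    ``ss_persistence`` is the probability of staying in the current
    secondary-structure state at each step of the 3-state Markov chain
    (higher = longer helices/strands/coils); ``exposure_rate`` and
    ``disorder_rate`` are the Bernoulli marginals of the exposed and
    disordered flags; coordinates are a Gaussian random walk smoothed over
    ``coord_smoothing`` residues.
    """

    ss_persistence: float = 0.8
    exposure_rate: float = 0.4
    disorder_rate: float = 0.1
    coord_smoothing: int = 5

    def __post_init__(self) -> None:
        for name in ("ss_persistence", "exposure_rate", "disorder_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if self.coord_smoothing < 1:
            raise ValidationError("coord_smoothing must be >= 1")


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one synthetic dataset.

    Defaults are the standard fixture: 300 proteins of 200-400 residues
    with uniform amino-acid usage under the trypsin rule - large enough
    for stable AUC estimates, small enough for minutes-scale CPU training.
    """

    n_proteins: int = 300
    length_range: tuple[int, int] = (200, 400)
    aa_frequencies: tuple[float, ...] = tuple([1.0 / 20] * 20)
    seed: int = 0
    rule: CleavageRule = field(default_factory=trypsin_rule)
    structure_seed: int = 1
    structure_params: StructureParams = field(default_factory=StructureParams)
    disulfide_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValidationError("n_proteins must be >= 1")
        lo, hi = self.length_range
        if not (1 <= lo <= hi):
            raise ValidationError(f"invalid length_range {self.length_range}")
        _validate_frequencies(self.aa_frequencies)


def _validate_frequencies(freqs: Sequence[float]) -> np.ndarray:
    arr = np.asarray(freqs, dtype=float)
    if arr.shape != (20,):
        raise ValidationError(f"aa_frequencies must have 20 entries, got {arr.shape}")
    if (arr < 0).any():
        raise ValidationError("aa_frequencies must be nonnegative")
    if abs(arr.sum() - 1.0) > 1e-9:
        raise ValidationError(f"aa_frequencies must sum to 1, got {arr.sum()!r}")
    return arr


def generate_protein(
    length: int,
    aa_frequencies: Sequence[float] | None = None,
    seed: int = 0,
    protein_id: str = "SYN1",
) -> ProteinRecord:
    """Draw a protein sequence i.i.d. from ``aa_frequencies`` (seeded)."""
    if length < 1:
        raise ValidationError("length must be >= 1")
    if aa_frequencies is None:
        aa_frequencies = [1.0 / 20] * 20
    freqs = _validate_frequencies(aa_frequencies)
    rng = np.random.default_rng(seed)
    letters = rng.choice(list(STANDARD_AA), size=length, p=freqs / freqs.sum())
    return ProteinRecord(id=protein_id, sequence="".join(letters))


def rule_sites(protein: ProteinRecord, rule: CleavageRule) -> list[int]:
    """Deterministic enumeration of the licensed sites of ``rule``.

    This is the noise-free oracle: :func:`apply_rule` with
    ``site_probability=1`` (and all overrides at 1) and ``decoy_rate=0``
    emits exactly these positions.
    """
    seq = protein.sequence
    return [
        p1
        for p1 in range(1, protein.length)
        if rule.is_licensed(seq[p1 - 1], seq[p1])
    ]


def apply_rule(
    protein: ProteinRecord, rule: CleavageRule, seed: int = 0
) -> list[CleavageAnnotation]:
    """Stochastically emit cleavage annotations for one protein.

    Each candidate bond draws one uniform variate (in p1 order), so the
    output is fully determined by ``(protein.sequence, rule, seed)``.
    """
    seq = protein.sequence
    rng = np.random.default_rng(seed)
    u = rng.random(protein.length - 1) if protein.length > 1 else np.empty(0)
    out = []
    for p1 in range(1, protein.length):
        prob = rule.emission_probability(seq[p1 - 1], seq[p1])
        if u[p1 - 1] < prob:
            out.append(
                CleavageAnnotation(
                    protease=rule.name,
                    protein_id=protein.id,
                    p1=p1,
                    source=AnnotationSource.DATABASE,
                )
            )
    return out


def simulate_structure(
    protein: ProteinRecord,
    seed: int = 0,
    params: StructureParams | None = None,
) -> StructuralFeatures:
    """Generate plausible per-residue structural features (seeded).

    Secondary structure is a 3-state Markov chain with run-length
    persistence; exposure and disorder are independent Bernoulli fields;
    coordinates are a smoothed 3D Gaussian random walk.  This emulates the
    *shape* of predictor output (PSIPRED/DISOPRED/ACCPRO-style tracks),
    not real protein structure.
    """
    params = params or StructureParams()
    L = protein.length
    rng = np.random.default_rng(seed)

    ss_idx = np.empty(L, dtype=int)
    ss_idx[0] = rng.integers(3)
    stay = rng.random(L - 1) if L > 1 else np.empty(0)
    jumps = rng.integers(0, 3, size=max(L - 1, 0))
    for i in range(1, L):
        ss_idx[i] = ss_idx[i - 1] if stay[i - 1] < params.ss_persistence else jumps[i - 1]

    exposed = rng.random(L) < params.exposure_rate
    disordered = rng.random(L) < params.disorder_rate

    steps = rng.normal(size=(L, 3))
    walk = np.cumsum(steps, axis=0)
    coords = uniform_filter1d(walk, size=params.coord_smoothing, axis=0, mode="nearest")

    ss_names = ("coil", "strand", "helix")
    return StructuralFeatures(
        ss_class=tuple(ss_names[i] for i in ss_idx),
        exposure=tuple("exposed" if e else "buried" for e in exposed),
        disorder=tuple(bool(d) for d in disordered),
        coords=coords,
    )


def tryptic_digest(protein: ProteinRecord, missed_cleavages: int = 0) -> list[PeptideHit]:
    """In-silico trypsin digest (after K/R, not before P).

    Returns every peptide delimited by the deterministic trypsin sites,
    including variants spanning up to ``missed_cleavages`` internal sites.
    With 0 missed cleavages the peptides partition the sequence.
    """
    if missed_cleavages < 0:
        raise ValidationError("missed_cleavages must be >= 0")
    sites = rule_sites(protein, trypsin_rule())
    bounds = [0] + sites + [protein.length]
    hits = []
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + 2 + missed_cleavages, len(bounds))):
            pep = protein.sequence[bounds[i]:bounds[j]]
            if pep:
                hits.append(PeptideHit(protein_id=protein.id, peptide=pep))
    return hits


@dataclass(frozen=True)
class SyntheticDataset:
    """A generated cohort: proteins, rule annotations, simulated features."""

    proteins: tuple[ProteinRecord, ...]
    annotations: tuple[CleavageAnnotation, ...]
    features: Mapping[str, StructuralFeatures]
    config: SimConfig

    @property
    def registry(self) -> ProteaseRegistry:
        return ProteaseRegistry.from_ids([self.config.rule.name])

    @property
    def protein_map(self) -> dict[str, ProteinRecord]:
        return {p.id: p for p in self.proteins}

    def imbalance_report(self) -> dict[str, float]:
        """Positives vs candidate universe, mirroring real-data imbalance."""
        n_candidates = sum(max(p.length - 1, 0) for p in self.proteins)
        n_pos = len(self.annotations)
        return {
            "n_candidates": n_candidates,
            "n_positives": n_pos,
            "n_negatives": n_candidates - n_pos,
            "positive_fraction": n_pos / n_candidates if n_candidates else 0.0,
        }


def generate_dataset(config: SimConfig) -> SyntheticDataset:
    """Generate a full synthetic cohort, reproducible from the config seeds.

    Per-protein seeds are drawn from top-level generators seeded with
    ``config.seed`` (sequences, lengths, rule noise) and
    ``config.structure_seed`` (features), so the whole dataset is a pure
    function of the config.
    """
    master = np.random.default_rng(config.seed)
    struct_master = np.random.default_rng(config.structure_seed)
    lo, hi = config.length_range

    proteins: list[ProteinRecord] = []
    annotations: list[CleavageAnnotation] = []
    features: dict[str, StructuralFeatures] = {}
    width = len(str(config.n_proteins))
    for i in range(config.n_proteins):
        length = int(master.integers(lo, hi + 1))
        seq_seed = int(master.integers(0, 2**31 - 1))
        rule_seed = int(master.integers(0, 2**31 - 1))
        struct_seed = int(struct_master.integers(0, 2**31 - 1))
        pid = f"SYN{i + 1:0{width}d}"
        protein = generate_protein(length, config.aa_frequencies, seq_seed, protein_id=pid)
        if config.disulfide_rate > 0:
            protein = _add_disulfides(protein, config.disulfide_rate, rule_seed ^ 0x5F5F)
        proteins.append(protein)
        annotations.extend(apply_rule(protein, config.rule, rule_seed))
        features[pid] = simulate_structure(protein, struct_seed, config.structure_params)

    return SyntheticDataset(
        proteins=tuple(proteins),
        annotations=tuple(annotations),
        features=features,
        config=config,
    )


def _add_disulfides(protein: ProteinRecord, rate: float, seed: int) -> ProteinRecord:
    """Pair up a random subset of cysteines as disulfide bonds."""
    rng = np.random.default_rng(seed)
    cys = [i + 1 for i, aa in enumerate(protein.sequence) if aa == "C"]
    rng.shuffle(cys)
    pairs = set()
    for a, b in zip(cys[::2], cys[1::2]):
        if rng.random() < rate:
            pairs.add(tuple(sorted((a, b))))
    return replace(protein, disulfide_pairs=frozenset(pairs))


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the dataset in the package's FASTA/TSV dialects.

    Output is byte-stable for a fixed config (used by the CLI determinism
    contract).  Returns the paths written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "proteins.fasta",
        "annotations": out / "cleavage_sites.tsv",
        "features": out / "structure_features.tsv",
        "disulfides": out / "disulfides.tsv",
    }
    write_fasta(dataset.proteins, paths["fasta"])
    write_cleavage_table(sorted(dataset.annotations), paths["annotations"])
    write_feature_table(dataset.features, paths["features"])
    write_disulfide_table(
        {p.id: p.disulfide_pairs for p in dataset.proteins if p.disulfide_pairs},
        paths["disulfides"],
    )
    return paths


def write_feature_table(
    features: Mapping[str, StructuralFeatures], path: str | Path
) -> None:
    import pandas as pd

    rows = []
    for pid in sorted(features):
        feat = features[pid]
        for i in range(len(feat)):
            rows.append(
                {
                    "protein_id": pid,
                    "pos": i + 1,
                    "ss": feat.ss_class[i],
                    "exposure": feat.exposure[i],
                    "disorder": int(feat.disorder[i]),
                    "x": round(float(feat.coords[i, 0]), 6),
                    "y": round(float(feat.coords[i, 1]), 6),
                    "z": round(float(feat.coords[i, 2]), 6),
                }
            )
    pd.DataFrame(
        rows, columns=["protein_id", "pos", "ss", "exposure", "disorder", "x", "y", "z"]
    ).to_csv(path, sep="\t", index=False)
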