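"""Synthetic RNA-seq dataset generator with planted structure.

Emulates the study design the pipeline targets: 3 tissues (testicular
parenchyma TP, head epididymis HE, tail epididymis TE) x 4 animals = 12
bulk libraries quantified over a mixed mRNA / small-RNA transcriptome.
Counts follow a negative-binomial model (variance = mu + mu^2 * dispersion)
on top of a log2-scale mean structure carrying

* planted differentially expressed transcripts per tissue pair,
* planted small-RNA regulators coupled to target mRNAs through a shared
  per-sample latent factor (sign-flipped for repressed targets), and
* multiplicative per-library offsets (2^offset) that the normalization
  stage is expected to remove.

Sequences (mature miRNAs and target cDNAs) are generated so that every
planted regulator-target pair carries extended complementarity anchored on
a canonical seed site, while non-target sequences are rejection-sampled to
contain no seed match for any planted miRNA. Everything is deterministic
given ``SimConfig.seed``.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix
from .seq import revcomp_rna

# biotype mix of a bulk testis/epididymis library (mRNA-dominated, ~11%
# small RNAs split roughly evenly across miRNA/snRNA/snoRNA)
BULK_BIOTYPE_PROPORTIONS = {
    "mRNA": 0.85,
    "miRNA": 0.04,
    "snRNA": 0.035,
    "snoRNA": 0.033,
    "misc": 0.042,
}

# default panel: small-RNA-focused, with the mRNA complement sized so a
# planted regulator's targets make up most of the DE mRNA list. Regulator
# recovery at n=4 replicates is only statistically possible when the
# candidate-target list is not dominated by unrelated DE mRNAs; the bulk
# mix above remains available for composition-focused runs.
DEFAULT_BIOTYPE_PROPORTIONS = {
    "mRNA": 0.10,
    "miRNA": 0.60,
    "snRNA": 0.15,
    "snoRNA": 0.15,
}

DEFAULT_TISSUES = ("TP", "HE", "TE")

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """Knobs of the synthetic dataset.

    ``regulator_correlation`` is the within-tissue co-expression strength
    induced between a regulator and its targets via the shared latent
    factor; ``regulator_active_tissues`` restricts the coupling to a subset
    of tissues (None = the first tissue only), which is what creates
    differential wiring for the RIF stage; pass the full tissue list to
    couple everywhere. ``regulator_log2fc`` is the tissue effect planted on
    regulators and their targets so that both enter the DE lists.
    """

    n_transcripts: int = 400
    biotype_proportions: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BIOTYPE_PROPORTIONS)
    )
    n_animals: int = 4
    tissues: Sequence[str] = DEFAULT_TISSUES
    n_de_per_pair: int = 35
    log2fc_de: float = 2.0
    n_regulators: int = 1
    targets_per_regulator: int = 20
    regulator_correlation: float = 0.95
    regulator_active_tissues: Optional[Sequence[str]] = None
    regulator_log2fc: float = 3.5
    repressed_target_fraction: float = 1.0
    nb_dispersion: float = 0.02
    lib_size_range: Tuple[int, int] = (800_000, 1_200_000)
    library_offsets: Dict[str, float] = field(
        default_factory=lambda: {"L1": 0.0, "L2": 0.5}
    )
    utr_length: int = 300
    planted_site_type: str = "8mer"
    mirna_length: int = 22
    base_log2_mean: float = 5.0
    base_log2_sd: float = 1.5
    biological_log2_sd: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        if self.n_transcripts <= 0:
            raise ConfigurationError("n_transcripts must be positive")
        total = sum(self.biotype_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"biotype proportions sum to {total}, expected 1"
            )
        unknown = set(self.biotype_proportions) - {
            "mRNA",
            "miRNA",
            "snRNA",
            "snoRNA",
            "misc",
        }
        if unknown:
            raise ConfigurationError(f"unknown biotype labels {sorted(unknown)}")
        if self.n_de_per_pair > self.n_transcripts:
            raise ConfigurationError("n_de_per_pair exceeds n_transcripts")
        if not -1.0 <= self.regulator_correlation <= 1.0:
            raise ConfigurationError("|regulator_correlation| must be <= 1")
        if self.log2fc_de < 0 or self.nb_dispersion <= 0:
            raise ConfigurationError("effect size must be >= 0, dispersion > 0")
        if self.n_animals <= 0 or len(self.tissues) < 2:
            raise ConfigurationError("need >= 1 animal and >= 2 tissues")
        if not 0.0 <= self.repressed_target_fraction <= 1.0:
            raise ConfigurationError("repressed_target_fraction must be in [0, 1]")
        if self.planted_site_type not in SITE_TYPES:
            raise ConfigurationError(
                f"planted_site_type must be one of {SITE_TYPES}"
            )
        if self.lib_size_range[0] <= 0 or self.lib_size_range[1] < self.lib_size_range[0]:
            raise ConfigurationError("invalid lib_size_range")
        if self.regulator_active_tissues is not None:
            bad = set(self.regulator_active_tissues) - set(self.tissues)
            if bad:
                raise ConfigurationError(f"unknown active tissues {sorted(bad)}")


@dataclass
class SimTruth:
    """Ground truth of the planted structure, for recovery tests.

    ``de_sets`` maps comparison label ("A/B") to {transcript_id: signed
    log2 effect, positive = up in the first-named tissue}; ``regulator_map``
    maps regulator id to a list of (target_id, sign); ``planted_sites``
    records (mirna_id, target_id, site_type, start) with ``start`` the
    0-based position of the seed-site sequence on the target.
    """

    de_sets: Dict[str, Dict[str, float]]
    regulator_map: Dict[str, List[Tuple[str, int]]]
    planted_sites: List[Tuple[str, str, str, int]]

    def to_dict(self) -> dict:
        return {
            "de_sets": self.de_sets,
            "regulator_map": {k: [list(t) for t in v] for k, v in self.regulator_map.items()},
            "planted_sites": [list(t) for t in self.planted_sites],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimTruth":
        return cls(
            de_sets=d["de_sets"],
            regulator_map={
                k: [(t, int(s)) for t, s in v] for k, v in d["regulator_map"].items()
            },
            planted_sites=[(m, t, st, int(p)) for m, t, st, p in d["planted_sites"]],
        )


def comparison_label(t1: str, t2: str) -> str:
    return f"{t1}/{t2}"


def tissue_pairs(tissues: Sequence[str]) -> List[Tuple[str, str]]:
    """Pairwise comparisons in the conventional order (HE/TE, HE/TP, TE/TP
    for the default tissue set): lexicographic on the labels."""
    labels = sorted(tissues)
    return [
        (labels[i], labels[j])
        for i in range(len(labels))
        for j in range(i + 1, len(labels))
    ]


def simulate_dataset(
    config: SimConfig,
) -> Tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame, SimTruth]:
    """Generate (counts matrix, annotation, sample sheet, truth).

    Counts are NB-distributed around per-sample means that combine baseline
    abundance, planted tissue effects, the regulator latent factor and the
    library offsets. The same config (same seed) always yields the same
    output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n = config.n_transcripts
    tissues = list(config.tissues)
    n_samples = config.n_animals * len(tissues)

    # --- annotation -------------------------------------------------------
    biotypes = _assign_biotypes(config, rng)
    ids = _make_ids(biotypes)
    lengths = np.where(
        np.isin(biotypes, ["miRNA", "snRNA", "snoRNA"]),
        rng.integers(60, 300, size=n),
        rng.integers(500, 5000, size=n),
    )
    annotation = pd.DataFrame(
        {
            "transcript_id": ids,
            "biotype": biotypes,
            "length_bp": lengths,
            "is_tf": False,
        }
    ).set_index("transcript_id", drop=False)

    # --- sample sheet -----------------------------------------------------
    libraries = sorted(config.library_offsets) or ["L1"]
    rows = []
    for a in range(config.n_animals):
        lib = libraries[(a * len(libraries)) // config.n_animals]
        for t in tissues:
            rows.append(
                {
                    "sample_id": f"A{a + 1}_{t}",
                    "animal": f"A{a + 1}",
                    "tissue": t,
                    "library": lib,
                }
            )
    samples = pd.DataFrame(rows).set_index("sample_id", drop=False)

    # --- log2 mean structure ---------------------------------------------
    base = rng.normal(config.base_log2_mean, config.base_log2_sd, size=n)
    log2_mu = np.tile(base[:, None], (1, n_samples))  # transcripts x samples
    tissue_of = samples["tissue"].to_numpy()

    truth_de: Dict[str, Dict[str, float]] = {}
    de_pool = rng.permutation(n)
    pool_pos = 0
    pairs = tissue_pairs(tissues)
    regulator_map: Dict[str, List[Tuple[str, int]]] = {}

    # reserve regulators (small RNAs) and targets (mRNAs) before generic DE
    small_idx = np.flatnonzero(np.isin(biotypes, ["miRNA", "snRNA", "snoRNA"]))
    mrna_idx = np.flatnonzero(biotypes == "mRNA")
    mirna_idx = np.flatnonzero(biotypes == "miRNA")
    if config.n_regulators > 0:
        if len(mirna_idx) < config.n_regulators:
            raise ConfigurationError("not enough miRNA transcripts for regulators")
        if len(mrna_idx) < config.n_regulators * config.targets_per_regulator:
            raise ConfigurationError("not enough mRNA transcripts for targets")
    reg_idx = rng.choice(mirna_idx, size=config.n_regulators, replace=False)
    available_targets = rng.permutation(mrna_idx)
    taken = set(reg_idx.tolist())
    target_assignment: Dict[int, List[Tuple[int, int]]] = {}
    ptr = 0
    for r in reg_idx:
        targets: List[Tuple[int, int]] = []
        while len(targets) < config.targets_per_regulator:
            t = int(available_targets[ptr])
            ptr += 1
            if t in taken:
                continue
            taken.add(t)
            n_repressed = round(
                config.repressed_target_fraction * config.targets_per_regulator
            )
            sign = -1 if len(targets) < n_repressed else 1
            targets.append((t, sign))
        target_assignment[int(r)] = targets
        regulator_map[ids[int(r)]] = [(ids[t], s) for t, s in targets]

    # planted regulator module: strong tissue contrast so regulator and
    # targets are DE, targets sign-matched on the count scale
    active = (
        set(config.regulator_active_tissues)
        if config.regulator_active_tissues is not None
        else {tissues[0]}
    )
    module_pattern = np.where(tissue_of == tissues[0], 1.0, 0.0) - np.mean(
        tissue_of == tissues[0]
    )
    # total per-sample log2 noise around the mean: biological replicate
    # noise plus the NB mixing noise (variance ~ dispersion on the natural
    # log scale for well-expressed transcripts, / ln(2)^2 on log2)
    noise_sd = math.sqrt(
        config.biological_log2_sd**2 + config.nb_dispersion / math.log(2) ** 2
    )
    for r, targets in target_assignment.items():
        amp = config.regulator_log2fc
        # regulators under study are well expressed; pin the module above
        # the baseline so counting noise does not erode the correlation
        log2_mu[r] = config.base_log2_mean + 1.5
        log2_mu[r] += amp * module_pattern
        for t, sign in targets:
            log2_mu[t] = config.base_log2_mean + 1.5
            log2_mu[t] += sign * amp * module_pattern
        # shared latent factor -> within-tissue co-expression (differential
        # wiring when restricted to the active tissues). The factor is
        # standardized over the active samples so the realized (not just
        # nominal) coupling variance is fixed even at n=4 replicates; the
        # amplitude is calibrated against the total log2 noise (biological
        # plus NB mixing) so the regulator-target correlation comes out at
        # the configured value.
        rho = abs(config.regulator_correlation)
        if rho > 0:
            mask = np.isin(tissue_of, list(active)).astype(float)
            act = mask > 0
            f = _standardized_latent(rng, n_samples, act)
            amp = noise_sd * math.sqrt(rho / max(1.0 - rho, 1e-6))
            log2_mu[r] += amp * f * mask
            for t, sign in targets:
                log2_mu[t] += sign * amp * f * mask

    # record regulator-module DE truth (regulator + targets DE in every pair
    # contrasting tissues[0] against another tissue)
    for t1, t2 in pairs:
        label = comparison_label(t1, t2)
        truth_de[label] = {}
        p = module_pattern  # up in tissues[0]
        eff1 = 1.0 if t1 == tissues[0] else 0.0
        eff2 = 1.0 if t2 == tissues[0] else 0.0
        delta = config.regulator_log2fc * (eff1 - eff2)
        if delta != 0 and config.n_regulators > 0:
            for r, targets in target_assignment.items():
                truth_de[label][ids[r]] = delta
                for t, sign in targets:
                    truth_de[label][ids[t]] = sign * delta

    # generic planted DE transcripts per pair
    if config.log2fc_de > 0:
        for t1, t2 in pairs:
            label = comparison_label(t1, t2)
            chosen = []
            while len(chosen) < config.n_de_per_pair and pool_pos < n:
                cand = int(de_pool[pool_pos])
                pool_pos += 1
                if cand in taken:
                    continue
                taken.add(cand)
                chosen.append(cand)
            if len(chosen) < config.n_de_per_pair:
                raise ConfigurationError(
                    "not enough free transcripts to plant requested DE"
                )
            signs = np.where(np.arange(len(chosen)) % 2 == 0, 1.0, -1.0)
            in_t1 = tissue_of == t1
            in_t2 = tissue_of == t2
            for c, s in zip(chosen, signs):
                # symmetric half-effect on each tissue of the pair
                log2_mu[c, in_t1] += s * config.log2fc_de / 2
                log2_mu[c, in_t2] -= s * config.log2fc_de / 2
                truth_de[label][ids[c]] = float(s * config.log2fc_de)

    # biological replicate noise on the log2 scale
    log2_mu += rng.normal(0.0, config.biological_log2_sd, size=log2_mu.shape)

    # --- scale to library sizes, apply library offsets, NB sample ---------
    lib_sizes = rng.integers(
        config.lib_size_range[0], config.lib_size_range[1] + 1, size=n_samples
    ).astype(float)
    # pre-offset depth: the "mapped reads" a quantifier would report; the
    # library bias multiplies the counts but not this denominator, so RPKM
    # computed against it preserves the offset for the mixed model to find
    samples["mapped_reads"] = lib_sizes.astype(int)
    rel = np.exp2(log2_mu)
    rel /= rel.sum(axis=0, keepdims=True)
    mu = rel * lib_sizes[None, :]
    offsets = samples["library"].map(config.library_offsets).to_numpy(dtype=float)
    mu = mu * np.exp2(offsets)[None, :]

    phi = config.nb_dispersion
    size = 1.0 / phi  # NB "number of successes": variance = mu + phi * mu^2
    p = size / (size + mu)
    counts = rng.negative_binomial(size, p)

    counts_df = pd.DataFrame(counts, index=ids, columns=samples.index)
    matrix = ExpressionMatrix(counts_df, "counts")

    if config.log2fc_de == 0 and config.n_regulators == 0:
        truth_de = {comparison_label(t1, t2): {} for t1, t2 in pairs}

    truth = SimTruth(de_sets=truth_de, regulator_map=regulator_map, planted_sites=[])
    return matrix, annotation, samples, truth


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------


def simulate_sequences(
    config: SimConfig, truth: SimTruth
) -> Tuple[Dict[str, str], Dict[str, str], SimTruth]:
    """Generate (miRNA FASTA map, target cDNA FASTA map) for the planted pairs.

    Each planted (miRNA, target) pair's target carries, at a recorded
    position, a seed site of ``config.planted_site_type`` embedded in the
    reverse complement of the miRNA body (nt 2..end), giving both an exact
    seed match and a strongly hybridizing duplex. All other windows of all
    targets are rejection-sampled to contain no 6mer seed match for any
    planted miRNA. Returns an updated SimTruth with ``planted_sites`` filled.
    """
    config.validate()
    if config.utr_length < 30:
        raise ConfigurationError("utr_length must be >= 30 to place a site")
    rng = np.random.default_rng(_derive_seed(config.seed, "sequences"))

    if not truth.regulator_map:
        return {}, {}, truth

    bases = np.array(list("ACGU"))

    mirnas: Dict[str, str] = {}
    seeds6: Dict[str, str] = {}
    for reg in truth.regulator_map:
        while True:
            seq = "".join(rng.choice(bases, size=config.mirna_length))
            site = _full_site(seq, config.planted_site_type)
            # the planted insert must contain exactly one seed match for
            # this miRNA and none for previously drawn ones
            seed_rc = revcomp_rna(seq[1:7])
            if _count_occurrences(site, seed_rc) != 1:
                continue
            if any(seed in site for seed in seeds6.values()):
                continue
            if any(seed_rc in _full_site(s, config.planted_site_type) for s in mirnas.values()):
                continue
            mirnas[reg] = seq
            seeds6[reg] = seed_rc
            break

    forbidden = list(seeds6.values())
    targets: Dict[str, str] = {}
    planted: List[Tuple[str, str, str, int]] = []
    for reg, target_list in truth.regulator_map.items():
        seq = mirnas[reg]
        insert = _full_site(seq, config.planted_site_type)
        for target_id, _sign in target_list:
            if target_id in targets:
                continue
            background = _random_seq_without(
                rng, config.utr_length - len(insert), forbidden, bases
            )
            while True:
                pos = int(rng.integers(1, len(background) - 1))
                full = background[:pos] + insert + background[pos:]
                # insertion boundaries may create a spurious site
                counts = [_count_occurrences(full, f) for f in forbidden]
                if sum(counts) == 1:
                    break
                background = _random_seq_without(
                    rng, config.utr_length - len(insert), forbidden, bases
                )
            targets[target_id] = full
            site_start, site_len = _site_coords(
                pos, len(seq), config.planted_site_type
            )
            planted.append((reg, target_id, config.planted_site_type, site_start))

    updated = SimTruth(
        de_sets=truth.de_sets,
        regulator_map=truth.regulator_map,
        planted_sites=sorted(planted),
    )
    return mirnas, targets, updated


def _full_site(mirna: str, site_type: str) -> str:
    """Target-strand insert: revcomp of miRNA nt 2..end, with the m8 and t1
    positions adjusted to realize the requested canonical site type."""
    body = revcomp_rna(mirna[1:])  # ends with revcomp(seed nt2-7)
    m8_pos = len(body) - 7  # complement of miRNA nt 8
    if site_type in ("7mer-A1", "6mer"):
        body = body[:m8_pos] + _mismatch(body[m8_pos]) + body[m8_pos + 1 :]
    t1 = "A" if site_type in ("8mer", "7mer-A1") else _non_a(mirna)
    return body + t1


def _site_coords(insert_pos: int, mirna_len: int, site_type: str) -> Tuple[int, int]:
    """0-based start and length of the canonical site within the target,
    given where the full insert begins."""
    body_len = mirna_len - 1
    if site_type == "8mer":
        return insert_pos + body_len - 7, 8
    if site_type == "7mer-m8":
        return insert_pos + body_len - 7, 7
    if site_type == "7mer-A1":
        return insert_pos + body_len - 6, 7
    return insert_pos + body_len - 6, 6  # 6mer


_COMPLEMENT_MISMATCH = {"A": "C", "C": "A", "G": "U", "U": "G"}


def _mismatch(base: str) -> str:
    # replacement that can neither pair (WC or G:U) with the original
    # partner nor re-create an A at the position
    return _COMPLEMENT_MISMATCH.get(base, "C")


def _non_a(mirna: str) -> str:
    return "C"


def _random_seq_without(rng, length: int, forbidden: List[str], bases) -> str:
    for _ in range(1000):
        seq = "".join(rng.choice(bases, size=length))
        if not any(f in seq for f in forbidden):
            return seq
    raise RuntimeError("rejection sampling failed; forbidden motifs too dense")


def _count_occurrences(hay: str, needle: str) -> int:
    count = start = 0
    while True:
        i = hay.find(needle, start)
        if i < 0:
            return count
        count += 1
        start = i + 1


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _standardized_latent(rng, n_samples: int, active: np.ndarray) -> np.ndarray:
    f = rng.normal(0.0, 1.0, size=n_samples)
    if active.sum() >= 2 and f[active].std() > 0:
        f[active] = (f[active] - f[active].mean()) / f[active].std()
    return f


def _assign_biotypes(config: SimConfig, rng) -> np.ndarray:
    n = config.n_transcripts
    labels = list(config.biotype_proportions)
    fracs = np.array([config.biotype_proportions[b] for b in labels])
    counts = np.floor(fracs * n).astype(int)
    # distribute the rounding remainder to the largest fractional parts
    rem = n - counts.sum()
    order = np.argsort(-(fracs * n - counts))
    for i in range(rem):
        counts[order[i % len(labels)]] += 1
    biotypes = np.repeat(labels, counts)
    rng.shuffle(biotypes)
    return biotypes


def _make_ids(biotypes: np.ndarray) -> List[str]:
    prefix = {
        "mRNA": "gene",
        "miRNA": "mir",
        "snRNA": "snrna",
        "snoRNA": "snorna",
        "misc": "misc",
    }
    counters: Dict[str, int] = {}
    ids = []
    for b in biotypes:
        counters[b] = counters.get(b, 0) + 1
        ids.append(f"{prefix[b]}-{counters[b]:04d}")
    return ids


def _derive_seed(seed: int, label: str) -> int:
    return (int(seed) * 1_000_003 + zlib.crc32(label.encode())) % (2**31 - 1)
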