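"""Synthetic wild + cultivated panel generator with known ground truth.

Generates one wild panel and several cultivated panels over a shared SNP
map, with three features that drive every downstream analysis stage:

* **domestication sweeps** — a configurable fraction of SNPs whose
  cultivated allele frequency is displaced toward fixation relative to
  the wild panel, producing the large wild-vs-cultivated divergence
  (F_ST of roughly 0.3-0.4) seen between *G. soja* and *G. max*;
* **shared cultivated ancestry** — all cultivated panels derive from one
  post-sweep frequency vector plus small per-panel noise, so
  between-cultivated F_ST stays low (order 0.01-0.06);
* **a QTL-controlled ordinal trait** — an additive liability over a
  handful of QTL SNPs, thresholded into the 1-5 open-pod rating scale at
  a configured heritability.

Accessions are simulated as highly inbred lines: genotypes are
homozygous draws from the panel allele frequency, with a small fraction
of calls re-labelled heterozygous to emulate residual heterozygosity
(these are the calls the QC step later converts to missing).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import GenotypePanel, HET, HOM_A, HOM_B, MISSING
from .traits import TraitRecord, rating_to_percent, arcsine_transform

__all__ = ["SimulationConfig", "TruthSet", "simulate_panels", "simulate_trait"]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic wild/cultivated study design.

    Defaults emulate the structure of the real panels: 20 chromosomes of
    biallelic SNPs, one strongly differentiated wild panel plus several
    related cultivated panels, a high-heritability ordinal trait driven
    by a handful of QTLs, sparse missingness and rare heterozygotes.
    """

    n_wild: int = 200
    panel_sizes: tuple[int, ...] = (200, 200)
    n_chrom: int = 20
    snps_per_chrom: int = 50
    chrom_length_bp: int = 50_000_000
    sweep_fraction: float = 0.05
    sweep_shift: float = 0.8
    n_qtl: int = 10
    qtl_effect_sd: float = 1.0
    heritability: float = 0.8
    missing_rate: float = 0.02
    het_rate: float = 0.01
    maf_floor: float = 0.05
    panel_freq_noise_sd: float = 0.02
    rating_cutpoints: tuple[float, float, float, float] = (-0.8, -0.25, 0.25, 0.8)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sweep_fraction", "sweep_shift", "heritability",
                     "missing_rate", "het_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        if not 0.0 <= self.maf_floor < 0.5:
            raise ValueError("maf_floor must lie in [0, 0.5)")
        if not self.panel_sizes:
            raise ValueError("panel_sizes must be nonempty")
        if self.n_wild < 2 or any(s < 2 for s in self.panel_sizes):
            raise ValueError("panels need at least 2 accessions")
        cp = self.rating_cutpoints
        if len(cp) != 4 or any(a >= b for a, b in zip(cp, cp[1:])):
            raise ValueError("rating_cutpoints must be 4 strictly increasing values")
        if self.n_qtl > self.n_chrom * self.snps_per_chrom:
            raise ValueError("n_qtl exceeds total SNP count")

    @property
    def n_snps(self) -> int:
        return self.n_chrom * self.snps_per_chrom

    def to_file(self, path) -> None:
        """Write the configuration as a flat key = value text file."""
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                v = getattr(self, f.name)
                if isinstance(v, tuple):
                    v = ",".join(str(x) for x in v)
                fh.write(f"{f.name} = {v}\n")

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        """Read a configuration written by :meth:`to_file`."""
        kwargs = {}
        types = {f.name: f for f in dataclasses.fields(cls)}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, raw = line.partition("=")
                key, raw = key.strip(), raw.strip()
                if key not in types:
                    raise ValueError(f"unknown config key {key!r}")
                if key in ("panel_sizes", "rating_cutpoints"):
                    parts = [p for p in raw.split(",") if p]
                    cast = int if key == "panel_sizes" else float
                    kwargs[key] = tuple(cast(p) for p in parts)
                elif key in ("sweep_fraction", "sweep_shift", "qtl_effect_sd",
                             "heritability", "missing_rate", "het_rate",
                             "maf_floor", "panel_freq_noise_sd"):
                    kwargs[key] = float(raw)
                else:
                    kwargs[key] = int(raw)
        return cls(**kwargs)


@dataclass
class TruthSet:
    """Ground truth recorded while simulating, for scoring downstream calls."""

    qtl_snp_ids: list[str]
    qtl_effects: np.ndarray
    swept_snp_ids: list[str]
    #: accession -> additive genetic value (sum of effect x allele-B dose)
    breeding_values: dict[str, float]
    #: wild / cultivated reference-allele (allele A) frequency vectors
    wild_freqs: np.ndarray = field(repr=False, default=None)
    cultivated_freqs: dict[str, np.ndarray] = field(repr=False, default=None)
    realized_h2: float | None = None

    def bv_vector(self, panel: GenotypePanel) -> np.ndarray:
        return np.array([self.breeding_values[a] for a in panel.accession_ids])


_NUCS = np.array(list("ACGT"))


def _snp_map(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    chroms = np.repeat(np.arange(1, cfg.n_chrom + 1), cfg.snps_per_chrom)
    pos = np.concatenate([
        np.sort(rng.choice(
            np.arange(1, cfg.chrom_length_bp + 1), size=cfg.snps_per_chrom,
            replace=False))
        for _ in range(cfg.n_chrom)
    ])
    pair = np.array([rng.choice(4, size=2, replace=False)
                     for _ in range(cfg.n_snps)])
    return pd.DataFrame({
        "snp_id": [f"ss{c:02d}{i:05d}" for c, i in
                   zip(chroms, np.tile(np.arange(cfg.snps_per_chrom), cfg.n_chrom))],
        "chrom": chroms.astype(int),
        "pos": pos.astype(int),
        "allele_a": _NUCS[pair[:, 0]],
        "allele_b": _NUCS[pair[:, 1]],
    })


def _sample_calls(freq_a: np.ndarray, n_acc: int, cfg: SimulationConfig,
                  rng: np.random.Generator) -> np.ndarray:
    """Inbred-line genotypes: hom-A w.p. freq_a, then het/missing relabels."""
    u = rng.random((n_acc, freq_a.size))
    calls = np.where(u < freq_a[None, :], HOM_A, HOM_B).astype(np.int8)
    if cfg.het_rate > 0:
        calls[rng.random(calls.shape) < cfg.het_rate] = HET
    complete = calls.copy()
    if cfg.missing_rate > 0:
        calls[rng.random(calls.shape) < cfg.missing_rate] = MISSING
    return calls, complete


def simulate_panels(config: SimulationConfig) -> tuple[list[GenotypePanel], TruthSet]:
    """Simulate the wild panel plus cultivated panels and the truth set.

    Returns the panels (wild first, id ``"WILD"``, then ``"CULT1"`` ...)
    over an identical SNP set, and a :class:`TruthSet` holding QTL
    effects, swept SNP ids and every accession's true breeding value
    (computed from the complete, pre-missingness genotypes).
    """
    rng = np.random.default_rng(config.seed)
    snps = _snp_map(config, rng)
    m = config.n_snps

    # ancestral (wild) allele-A frequency
    wild_freq = rng.uniform(config.maf_floor, 1.0 - config.maf_floor, size=m)

    # sweeps: displace the shared cultivated frequency toward fixation,
    # in whichever direction leaves room for the full shift
    n_swept = int(round(config.sweep_fraction * m))
    swept_idx = rng.choice(m, size=n_swept, replace=False) if n_swept else np.array([], int)
    cult_base = wild_freq.copy()
    if n_swept:
        direction = np.where(wild_freq[swept_idx] <= 0.5, 1.0, -1.0)
        cult_base[swept_idx] = np.clip(
            wild_freq[swept_idx] + direction * config.sweep_shift, 0.0, 1.0)

    # QTLs drawn from non-swept SNPs when possible, so trait and sweep
    # ground truths stay separable
    candidates = np.setdiff1d(np.arange(m), swept_idx)
    if candidates.size < config.n_qtl:
        candidates = np.arange(m)
    qtl_idx = rng.choice(candidates, size=config.n_qtl, replace=False)
    qtl_effects = rng.normal(0.0, config.qtl_effect_sd, size=config.n_qtl)

    panels: list[GenotypePanel] = []
    breeding_values: dict[str, float] = {}
    cult_freqs: dict[str, np.ndarray] = {}

    def add_panel(pid: str, n_acc: int, freq_a: np.ndarray, prefix: str) -> None:
        calls, complete = _sample_calls(freq_a, n_acc, config, rng)
        ids = [f"{prefix}{i:04d}" for i in range(n_acc)]
        # allele-B dose from the complete matrix; hets count 1
        dose_b = np.where(complete == MISSING, 0, complete).astype(float)
        bv = dose_b[:, qtl_idx] @ qtl_effects
        breeding_values.update(zip(ids, bv))
        panels.append(GenotypePanel(pid, ids, snps.copy(), calls))

    add_panel("WILD", config.n_wild, wild_freq, "WS")
    for j, size in enumerate(config.panel_sizes, start=1):
        freq = cult_base
        if config.panel_freq_noise_sd > 0:
            freq = np.clip(
                cult_base + rng.normal(0, config.panel_freq_noise_sd, size=m),
                0.0, 1.0)
        pid = f"CULT{j}"
        cult_freqs[pid] = freq
        add_panel(pid, size, freq, f"CA{j}_")

    truth = TruthSet(
        qtl_snp_ids=list(snps["snp_id"].iloc[qtl_idx]),
        qtl_effects=qtl_effects,
        swept_snp_ids=list(snps["snp_id"].iloc[np.sort(swept_idx)]),
        breeding_values=breeding_values,
        wild_freqs=wild_freq,
        cultivated_freqs=cult_freqs,
    )
    return panels, truth


def simulate_trait(panel: GenotypePanel, truth: TruthSet,
                   config: SimulationConfig) -> list[TraitRecord]:
    """Ordinal 1-5 dehiscence ratings from a liability-threshold model.

    liability = (standardized breeding value) * sqrt(h2) + noise * sqrt(1-h2),
    thresholded at ``config.rating_cutpoints``.  At h2=1 the rating is a
    deterministic function of the QTL genotypes; at h2=0 it is pure noise.
    Records ``realized_h2`` (squared correlation of liability with the
    true breeding value) on the truth set.
    """
    h2 = config.heritability
    if not 0.0 <= h2 <= 1.0:
        raise ValueError(f"heritability {h2} outside [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 997]))
    bv = truth.bv_vector(panel)
    sd = bv.std()
    z = (bv - bv.mean()) / sd if sd > 0 else np.zeros_like(bv)
    noise = rng.standard_normal(len(bv))
    liability = np.sqrt(h2) * z + np.sqrt(1.0 - h2) * noise
    ratings = 1 + np.searchsorted(np.asarray(config.rating_cutpoints),
                                  liability, side="right")
    var_l = liability.var()
    truth.realized_h2 = float(np.corrcoef(liability, bv)[0, 1] ** 2) \
        if sd > 0 and var_l > 0 and h2 > 0 else 0.0
    out = []
    for acc, r in zip(panel.accession_ids, ratings.astype(int)):
        frac = rating_to_percent(int(r)) / 100.0
        out.append(TraitRecord(
            accession_id=acc, rating=float(r), open_pod_fraction=frac,
            transformed=arcsine_transform(frac)))
    return out
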