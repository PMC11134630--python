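"""Simulation configuration for the synthetic experimental-evolution study.

The defaults mirror the design of a highly replicated *Drosophila*
thermal-adaptation experiment: 10 replicate populations evolved from a
common ancestral gene pool, multiple-choice mating assays with 50 flies of
each sex per population and a 25-pair stopping rule, 12 cuticular
hydrocarbons (CHCs) detected in all samples, and a 3-population diallel
cross with Poisson-like progeny counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
import yaml


def _default_sex_effect(n_compounds: int) -> np.ndarray:
    """Dominant per-compound log-scale sex shift (cosine pattern, zero mean)."""
    k = np.arange(n_compounds)
    return 1.2 * np.cos(2 * np.pi * k / n_compounds)


def _default_evo_effect(n_compounds: int) -> np.ndarray:
    """Secondary evolution shift, orthogonal to the sex pattern."""
    k = np.arange(n_compounds)
    return 0.45 * np.sin(2 * np.pi * k / n_compounds)


@dataclass
class SimConfig:
    """Knobs for all four synthetic data modalities.

    Parameters
    ----------
    seed:
        Single global seed; every generator derives an independent
        substream from it, so seeded runs are bit-reproducible.
    n_replicates:
        Number of independently evolved replicate populations.
    n_flies_per_pop_per_sex, max_pairs, preference:
        Multiple-choice mating assay: flies of each sex released per
        population, the stopping rule (first ``max_pairs`` mating pairs),
        and the homotypic mating weight (1 = random mating; larger values
        mean stronger assortment).
    n_compounds, sex_effect, evo_effect, chc_noise_sd, chc_base_log:
        CHC profile generator: number of compounds, per-compound log-scale
        shifts for sex and for evolution, the log-scale sample noise, and
        the baseline log-abundance pattern (defaults to a ramp so one
        compound dominates, as real fly profiles do).
    n_genes, frac_reproduction_genes, shared_lfc_sd, replicate_lfc_sd,
    up_bias, nb_dispersion:
        RNA-seq count generator: genes simulated, the fraction designated
        as the "reproduction" gene set, log2 fold-change scales for the
        shared adaptive response and for the replicate-specific response
        (the latter injected only into reproduction genes, in 1-2 randomly
        chosen replicates per gene), the probability a replicate-specific
        shift is an up-regulation, and the NB dispersion phi in
        Var = mu + phi * mu^2.
    diallel_mean, diallel_within_advantage:
        Diallel progeny counts: Poisson mean of between-replicate crosses
        and the multiplicative advantage of within-replicate crosses.
    """

    seed: int = 0
    n_replicates: int = 10
    # choice assay
    n_flies_per_pop_per_sex: int = 50
    max_pairs: int = 25
    preference: float = 1.0
    # CHC profiles
    n_compounds: int = 12
    sex_effect: np.ndarray | None = None
    evo_effect: np.ndarray | None = None
    chc_noise_sd: float = 0.15
    chc_base_log: np.ndarray | None = None
    # expression counts
    n_genes: int = 2000
    frac_reproduction_genes: float = 0.1
    shared_lfc_sd: float = 0.5
    replicate_lfc_sd: float = 2.0
    up_bias: float = 0.9
    nb_dispersion: float = 0.2
    baseline_log2_mean: float = 6.0
    baseline_log2_sd: float = 2.0
    library_size: float = 1.0e6
    library_size_log_sd: float = 0.3
    # diallel cross
    diallel_mean: float = 24.0
    diallel_within_advantage: float = 0.09

    def __post_init__(self) -> None:
        if self.sex_effect is None:
            self.sex_effect = _default_sex_effect(self.n_compounds)
        if self.evo_effect is None:
            self.evo_effect = _default_evo_effect(self.n_compounds)
        if self.chc_base_log is None:
            self.chc_base_log = np.linspace(2.5, 0.0, self.n_compounds)
        self.sex_effect = np.asarray(self.sex_effect, dtype=float)
        self.evo_effect = np.asarray(self.evo_effect, dtype=float)
        self.chc_base_log = np.asarray(self.chc_base_log, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.preference < 1:
            raise ValueError("preference must be >= 1 (1 = random mating)")
        for name in ("chc_noise_sd", "shared_lfc_sd", "replicate_lfc_sd",
                     "nb_dispersion", "diallel_within_advantage"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.5 <= self.up_bias <= 1.0:
            raise ValueError("up_bias must lie in [0.5, 1]")
        if not 0.0 < self.frac_reproduction_genes < 1.0:
            raise ValueError("frac_reproduction_genes must lie in (0, 1)")
        if self.diallel_mean <= 0:
            raise ValueError("diallel_mean must be > 0")
        if not isinstance(self.n_genes, (int, np.integer)):
            raise ValueError("n_genes must be an integer")
        for vec, name in ((self.sex_effect, "sex_effect"),
                          (self.evo_effect, "evo_effect"),
                          (self.chc_base_log, "chc_base_log")):
            if len(vec) != self.n_compounds:
                raise ValueError(f"{name} must have length n_compounds")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent substream derived from the global seed."""
        return np.random.default_rng(np.random.SeedSequence(self.seed).spawn(stream + 1)[stream])

    @classmethod
    def from_yaml(cls, path: str) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown SimConfig keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str) -> None:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            out[f.name] = v.tolist() if isinstance(v, np.ndarray) else v
        with open(path, "w") as fh:
            yaml.safe_dump(out, fh, sort_keys=False)
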