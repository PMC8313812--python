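"""Synthetic paired FI/DI communities with planted co-response structure.

The generator emulates a paired irrigation experiment in one soil
compartment: every OTU has a log-normal baseline abundance, full-irrigation
(FI) replicates scatter around that baseline, and deficit-irrigation (DI)
replicates are additionally multiplied by an OTU- and replicate-specific
treatment multiplier.  OTUs planted in a *module* share (through a latent
per-replicate factor) the replicate pattern of their log multipliers, so
their DI/FI abundance-ratio vectors are correlated — positively within a
positive module, negatively between opposite-signed members of a negative
module.  Background OTUs get independent multipliers and zero inflation.

The latent factor realizations are standardized (exact zero mean, unit
variance across replicates), so the module ``strength`` in [0, 1] maps
directly onto the ratio-space correlation the network stage consumes: at
strength 1 module members' log-ratio vectors are correlated at
2 sigma_f^2 / (2 sigma_f^2 + 2 sigma_e^2) ~= 0.98 under the default
scales, and at strength s the shared fraction scales with s^2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .tables import Lineage, OtuTable, SampleDesign, TaxonomyMap

__all__ = ["ModuleSpec", "SyntheticTruth", "generate_paired_design", "generate_study"]

# Log-scale magnitudes: latent replicate factor, replicate measurement
# noise, OTU-level treatment response, baseline spread.
SIGMA_FACTOR = 1.5
SIGMA_NOISE = 0.2
SIGMA_RESPONSE = 0.5
BASELINE_MEAN_LOG = 5.0
BASELINE_SIGMA_LOG = 1.2
MODULE_BASELINE_MEAN_LOG = 6.0
MODULE_BASELINE_SIGMA_LOG = 0.6

_PHYLA_B = ["Proteobacteria", "Actinobacteria", "Acidobacteria", "Verrucomicrobia",
            "Planctomycetes", "Gemmatimonadetes", "Bacteroidetes", "Firmicutes"]
_PHYLA_F = ["Ascomycota", "Basidiomycota", "Mortierellomycota", "Chytridiomycota"]


@dataclass(frozen=True)
class ModuleSpec:
    """A planted co-response module: ``size`` OTUs, ``sign`` +1 or -1."""

    size: int
    sign: int
    strength: float

    def __post_init__(self) -> None:
        if self.sign not in (1, -1):
            raise ValueError("module sign must be +1 or -1")
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError("module strength must lie in [0, 1]")
        if self.size < 2:
            raise ValueError("a module needs at least two OTUs")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated community."""

    modules: dict[str, int | None]            # otu_id -> module index (or None)
    member_signs: dict[str, int]              # otu_id -> +1 / -1 within its module
    planted_edges: set[tuple[str, str, int]]  # (otu_a, otu_b, expected edge sign)
    params: dict = field(default_factory=dict)

    def module_members(self, index: int) -> list[str]:
        return sorted(o for o, m in self.modules.items() if m == index)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "modules": self.modules,
            "member_signs": self.member_signs,
            "planted_edges": sorted(list(e) for e in self.planted_edges),
            "params": self.params,
        }
        Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def _standardized_normal(rng: np.random.Generator, n: int) -> np.ndarray:
    """n i.i.d. normals recentred/rescaled to exact mean 0, variance 1."""
    f = rng.standard_normal(n)
    f = f - f.mean()
    sd = f.std()
    if sd < 1e-12:  # pathological draw; fall back to a fixed spread pattern
        f = np.linspace(-1.0, 1.0, n)
        f = f - f.mean()
        sd = f.std()
    return f / sd


def generate_paired_design(
    n_bacteria: int = 120,
    n_fungi: int = 30,
    n_reps: int = 3,
    module_spec: list[ModuleSpec] | list[tuple[int, int, float]] | None = None,
    zero_rate: float = 0.3,
    seed: int = 0,
    compartment: str = "BS",
) -> tuple[OtuTable, TaxonomyMap, SampleDesign, SyntheticTruth]:
    """Generate one compartment's paired FI/DI count table with ground truth.

    Parameters
    ----------
    n_bacteria, n_fungi:
        OTU richness per kingdom.  Defaults are a desk-scale reduction of a
        real soil survey (thousands of bacterial, hundreds of fungal OTUs)
        that keeps the bacteria:fungi imbalance.
    n_reps:
        Replicates per treatment (study layout: 3 FI + 3 DI).
    module_spec:
        Planted modules, each ``ModuleSpec(size, sign, strength)`` (tuples
        accepted).  Modules are assigned to the lowest-index OTUs, bacteria
        first, and module members are exempt from zero inflation with a
        boosted baseline so they always survive prevalence filtering.
    zero_rate:
        Per-cell dropout probability applied to background OTUs only.
    seed:
        Seeds every draw; identical seeds give bit-identical output.
    """
    if n_reps < 2:
        raise ValueError("need at least two replicates per treatment")
    if not 0.0 <= zero_rate < 1.0:
        raise ValueError("zero_rate must lie in [0, 1)")
    modules = [m if isinstance(m, ModuleSpec) else ModuleSpec(*m) for m in (module_spec or [])]
    n_otus = n_bacteria + n_fungi
    if sum(m.size for m in modules) > n_otus:
        raise ValueError("module sizes exceed the number of OTUs")

    rng = np.random.default_rng(seed)
    otu_ids = [f"B{n:04d}" for n in range(n_bacteria)] + [f"F{n:04d}" for n in range(n_fungi)]

    # Module membership: consecutive OTUs, bacteria first.
    module_of = np.full(n_otus, -1)
    member_sign = np.zeros(n_otus, dtype=int)
    cursor = 0
    for mi, mod in enumerate(modules):
        idx = np.arange(cursor, cursor + mod.size)
        module_of[idx] = mi
        if mod.sign > 0:
            member_sign[idx] = 1
        else:  # split a negative module into two anticorrelated halves
            member_sign[idx[: mod.size // 2]] = 1
            member_sign[idx[mod.size // 2:]] = -1
        cursor += mod.size
    in_module = module_of >= 0

    baseline = np.where(
        in_module,
        rng.lognormal(MODULE_BASELINE_MEAN_LOG, MODULE_BASELINE_SIGMA_LOG, n_otus),
        rng.lognormal(BASELINE_MEAN_LOG, BASELINE_SIGMA_LOG, n_otus),
    )
    response = rng.normal(0.0, SIGMA_RESPONSE, n_otus)  # OTU-level drought response

    # Per-replicate biological variability of scale SIGMA_FACTOR on both
    # treatment sides.  Module members draw it from standardized per-module
    # latent factors (one over DI replicates — the co-response pattern — and
    # one over FI replicates), weighted sign * strength, so two members'
    # DI/FI ratio profiles share the (f_DI[r] - f_FI[s]) pattern across all
    # nine pairs; background OTUs fluctuate independently on both sides.
    f_di = np.vstack([_standardized_normal(rng, n_reps) for _ in modules]) \
        if modules else np.zeros((0, n_reps))
    f_fi = np.vstack([_standardized_normal(rng, n_reps) for _ in modules]) \
        if modules else np.zeros((0, n_reps))
    idio_di = rng.standard_normal((n_otus, n_reps))
    idio_fi = rng.standard_normal((n_otus, n_reps))
    log_di_shift = np.empty((n_otus, n_reps))
    log_fi_shift = np.empty((n_otus, n_reps))
    for i in range(n_otus):
        mi = module_of[i]
        if mi >= 0:
            s = modules[mi].strength
            g = member_sign[i]
            damp = np.sqrt(1.0 - s * s)
            log_di_shift[i] = SIGMA_FACTOR * (g * s * f_di[mi] + damp * idio_di[i])
            log_fi_shift[i] = SIGMA_FACTOR * (g * s * f_fi[mi] + damp * idio_fi[i])
        else:
            log_di_shift[i] = SIGMA_FACTOR * idio_di[i]
            log_fi_shift[i] = SIGMA_FACTOR * idio_fi[i]
    log_di_shift += response[:, None]  # OTU-level mean treatment response

    noise_fi = rng.normal(0.0, SIGMA_NOISE, (n_otus, n_reps))
    noise_di = rng.normal(0.0, SIGMA_NOISE, (n_otus, n_reps))
    fi = baseline[:, None] * np.exp(log_fi_shift + noise_fi)
    di = baseline[:, None] * np.exp(log_di_shift + noise_di)

    counts = np.rint(np.concatenate([fi, di], axis=1))
    if zero_rate > 0:
        drop = rng.random(counts.shape) < zero_rate
        drop[in_module] = False
        counts[drop] = 0.0

    sample_ids = [f"{compartment}-FI-{r + 1}" for r in range(n_reps)] + \
                 [f"{compartment}-DI-{r + 1}" for r in range(n_reps)]
    table = OtuTable(pd.DataFrame(counts, index=otu_ids, columns=sample_ids), "counts")

    lineages = {}
    for i, otu in enumerate(otu_ids):
        if i < n_bacteria:
            phylum = _PHYLA_B[i % len(_PHYLA_B)]
            kingdom = "Bacteria"
        else:
            phylum = _PHYLA_F[(i - n_bacteria) % len(_PHYLA_F)]
            kingdom = "Fungi"
        lineages[otu] = Lineage(kingdom=kingdom, phylum=phylum, order=f"{phylum}_order{i % 5}",
                                genus=f"{phylum}_genus{i % 11}")
    taxonomy = TaxonomyMap(lineages)

    design_rows = []
    for r in range(n_reps):
        design_rows.append((f"{compartment}-FI-{r + 1}", compartment, "FI", r + 1))
    for r in range(n_reps):
        design_rows.append((f"{compartment}-DI-{r + 1}", compartment, "DI", r + 1))
    design = SampleDesign(
        pd.DataFrame(
            [(c, t, rep) for _, c, t, rep in design_rows],
            index=[s for s, *_ in design_rows],
            columns=["compartment", "treatment", "replicate"],
        )
    )

    planted: set[tuple[str, str, int]] = set()
    for mi in range(len(modules)):
        members = [i for i in range(n_otus) if module_of[i] == mi]
        for a_pos, a in enumerate(members):
            for b in members[a_pos + 1:]:
                sign = int(member_sign[a] * member_sign[b])
                planted.add((otu_ids[a], otu_ids[b], sign))
    truth = SyntheticTruth(
        modules={otu_ids[i]: (int(module_of[i]) if module_of[i] >= 0 else None)
                 for i in range(n_otus)},
        member_signs={otu_ids[i]: int(member_sign[i]) for i in range(n_otus) if in_module[i]},
        planted_edges=planted,
        params={
            "n_bacteria": n_bacteria, "n_fungi": n_fungi, "n_reps": n_reps,
            "modules": [(m.size, m.sign, m.strength) for m in modules],
            "zero_rate": zero_rate, "seed": seed, "compartment": compartment,
        },
    )
    return table, taxonomy, design, truth


def generate_study(
    compartments: tuple[str, ...] = ("BS", "SRz", "TRz"),
    seed: int = 0,
    **kwargs,
) -> tuple[OtuTable, TaxonomyMap, SampleDesign, dict[str, SyntheticTruth]]:
    """Generate a full multi-compartment study (same OTU set, independent
    abundances per compartment) by stacking per-compartment tables."""
    truths: dict[str, SyntheticTruth] = {}
    frames = []
    taxonomy = None
    for k, comp in enumerate(compartments):
        table, taxonomy, design, truth = generate_paired_design(
            seed=seed + 1000 * k, compartment=comp, **kwargs
        )
        frames.append((table, design))
        truths[comp] = truth
    data = pd.concat([t.data for t, _ in frames], axis=1)
    design_frame = pd.concat([d.frame for _, d in frames], axis=0)
    return OtuTable(data, "counts"), taxonomy, SampleDesign(design_frame), truths
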