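"""Synthetic expression datasets with planted co-expression structure.

The generator emulates a two-color microarray study of a thermophilic
fermentative bacterium grown on five carbon-source regimes (glucose, xylose,
fructose, cellobiose, and a glucose+xylose mixture) sampled along the growth
curve, 33 arrays in total: mid-exponential phase for every substrate plus
early/mid/late series for glucose, xylose and the mixture, three biological
replicates each.

Planted structure, per module, follows a common-factor model: within each
sample, module members share a latent factor; condition responsiveness is a
mean shift in log2 units on the member genes under the module's responsive
conditions.  Loadings are calibrated so that the expected pairwise Pearson
correlation of members across the full sample axis — counting both the
shared mean pattern and the latent factor — equals the planted
``within_module_correlation``; combinations where the mean pattern alone
already exceeds the target are rejected as infeasible.
Background genes are independent noise; negative-control probes are pure
noise centred on zero.  An SNR table with random sub-threshold dropout cells
emulates unquantifiable spots.

Array-content constants mirror a 70-mer oligonucleotide array covering 2322
of 2365 annotated gene sequences (43 had no acceptable probe) with 20
negative-control probes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import (
    COG_LETTERS,
    ExpressionMatrix,
    GeneAnnotation,
    Sample,
    SampleDesign,
    ValidationError,
    write_annotations,
    write_design,
    write_expression,
)

#: Gene sequences used for probe design on the reference array.
DESIGNED_GENES = 2365
#: Sequences for which no acceptable probe could be designed.
UNDESIGNABLE_GENES = 43
#: Annotated gene sequences covered by the array (= designed - undesignable).
COVERED_GENES = DESIGNED_GENES - UNDESIGNABLE_GENES
#: Probes on the array (group-specific probes cover several paralogs).
N_PROBES = 2315
#: Probes designed from random human ORFs, used as negative controls.
DEFAULT_NEGATIVE_CONTROLS = 20

_SUBSTRATE_CODE = {
    "glucose": "G",
    "xylose": "X",
    "fructose": "F",
    "cellobiose": "C",
    "glucose_xylose": "GX",
}


def default_design() -> SampleDesign:
    """The 33-array design: 11 (substrate, phase) conditions x 3 replicates.

    Mid-phase profiles for all four single substrates and the glucose+xylose
    mixture, plus early and late phases for glucose, xylose and the mixture.
    Ordering is deterministic: growth-phase series first, then the remaining
    mid-phase substrates.
    """
    conditions: list[tuple[str, str]] = []
    for substrate in ("glucose", "xylose", "glucose_xylose"):
        for phase in ("early", "mid", "late"):
            conditions.append((substrate, phase))
    conditions.append(("fructose", "mid"))
    conditions.append(("cellobiose", "mid"))
    samples = []
    for substrate, phase in conditions:
        code = _SUBSTRATE_CODE[substrate]
        for rep in (1, 2, 3):
            samples.append(Sample(f"{code}_{phase}_{rep}", substrate, phase, rep))
    return SampleDesign(tuple(samples))


@dataclass(frozen=True)
class ModuleSpec:
    """One planted co-expression module.

    ``within_module_correlation`` is the target expected pairwise Pearson
    correlation of members across the full sample axis; ``mean_shift``
    (log2 units) is added to every member under each responsive condition.
    ``n_hubs`` members get a boosted factor loading so their correlations to
    the rest of the module are systematically higher — planted hub genes.
    """

    module_id: str
    size: int
    responsive_conditions: frozenset[tuple[str, str]] = frozenset()
    mean_shift: float = 2.0
    within_module_correlation: float = 0.95
    n_hubs: int = 0

    def __post_init__(self) -> None:
        if self.size < 5:
            raise ValidationError(f"module {self.module_id}: size must be >= 5")
        r = self.within_module_correlation
        if not (0.0 <= r < 1.0):
            raise ValidationError(
                f"module {self.module_id}: within_module_correlation must be in [0, 1)"
            )
        if not (0 <= self.n_hubs <= self.size):
            raise ValidationError(f"module {self.module_id}: invalid n_hubs")


@dataclass(frozen=True)
class SyntheticSpec:
    n_genes: int = COVERED_GENES
    design: SampleDesign = field(default_factory=default_design)
    modules: tuple[ModuleSpec, ...] = ()
    n_negative_controls: int = DEFAULT_NEGATIVE_CONTROLS
    noise_sd: float = 0.25
    snr_dropout_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        ids = [m.module_id for m in self.modules]
        if len(set(ids)) != len(ids):
            raise ValidationError("module ids must be unique")
        planted = sum(m.size for m in self.modules)
        if planted + self.n_negative_controls > self.n_genes:
            raise ValidationError(
                f"module sizes ({planted}) + negative controls "
                f"({self.n_negative_controls}) exceed n_genes ({self.n_genes})"
            )
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        if not (0.0 <= self.snr_dropout_rate < 1.0):
            raise ValidationError("snr_dropout_rate must be in [0, 1)")


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated dataset."""

    module_of: dict[str, str | None]          # gene -> module id (None = background)
    true_mean: dict[str, dict[tuple[str, str], float]]  # gene -> condition -> mean log2R
    planted_correlation: dict[str, float]     # module id -> target r
    hub_genes: dict[str, list[str]]           # module id -> planted hub gene ids
    negative_controls: list[str]
    seed: int

    def members(self, module_id: str) -> list[str]:
        return [g for g, m in self.module_of.items() if m == module_id]

    def planted_genes(self) -> list[str]:
        return [g for g, m in self.module_of.items() if m is not None]


def _gene_ids(spec: SyntheticSpec) -> tuple[list[str], list[str]]:
    n_regular = spec.n_genes - spec.n_negative_controls
    regular = [f"syn{i:04d}" for i in range(1, n_regular + 1)]
    controls = [f"negctrl{i:02d}" for i in range(1, spec.n_negative_controls + 1)]
    return regular, controls


def simulate(spec: SyntheticSpec) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Draw one dataset from the generative model; reproducible from the seed.

    Member gene value = mean_shift(condition) + a * factor + u * eps with one
    standard-normal factor per module per sample and a^2 + u^2 = noise_sd^2;
    the factor variance a^2 is solved so (mean-pattern variance + a^2) /
    total variance equals the planted correlation.  Hub members use the
    boosted share ``1 - (1-r)/4``, so their correlation to the rest of the
    module is systematically higher and they acquire systematically higher
    degree at any cutoff inside the module's correlation band.
    """
    rng = np.random.default_rng(spec.seed)
    n_samples = len(spec.design)
    regular, controls = _gene_ids(spec)
    genes = regular + controls
    n_genes = len(genes)

    values = rng.normal(0.0, spec.noise_sd, size=(n_genes, n_samples))

    module_of: dict[str, str | None] = {g: None for g in genes}
    true_mean: dict[str, dict[tuple[str, str], float]] = {g: {} for g in genes}
    planted_r: dict[str, float] = {}
    hub_genes: dict[str, list[str]] = {}

    cond_of_col = [s.condition for s in spec.design.samples]
    sigma2 = spec.noise_sd**2
    cursor = 0
    for mod in spec.modules:
        members = regular[cursor : cursor + mod.size]
        cursor += mod.size
        r = mod.within_module_correlation
        planted_r[mod.module_id] = r
        hubs = members[: mod.n_hubs]
        hub_genes[mod.module_id] = list(hubs)

        shift = np.zeros(n_samples)
        for j, cond in enumerate(cond_of_col):
            if cond in mod.responsive_conditions:
                shift[j] = mod.mean_shift
        # the deterministic mean pattern is itself shared variance between
        # members; loadings are solved so the total shared share (mean
        # pattern + latent factor) over total variance hits the target r
        v_mean = float(np.var(shift))
        total = v_mean + sigma2

        def factor_var(share: float) -> float:
            fv = share * total - v_mean
            if fv < -1e-12:
                raise ValidationError(
                    f"module {mod.module_id}: within_module_correlation "
                    f"{share:.3g} infeasible — the condition mean pattern alone "
                    f"contributes a correlation of {v_mean / total:.3g} at "
                    f"noise_sd {spec.noise_sd}"
                )
            return max(fv, 0.0)

        r_hub = 1.0 - (1.0 - r) / 4.0
        a2 = np.full(mod.size, factor_var(r))
        if mod.n_hubs:
            a2[: mod.n_hubs] = factor_var(r_hub)
        loading = np.sqrt(a2)
        unique = np.sqrt(np.maximum(sigma2 - a2, 0.0))
        factor = rng.standard_normal(n_samples)
        eps = rng.standard_normal((mod.size, n_samples))
        rows = slice(cursor - mod.size, cursor)  # members are contiguous
        block = loading[:, None] * factor[None, :] + unique[:, None] * eps
        values[rows, :] = block + shift[None, :]
        for g in members:
            module_of[g] = mod.module_id
            for cond in set(cond_of_col):
                true_mean[g][cond] = mod.mean_shift if cond in mod.responsive_conditions else 0.0

    for g in regular[cursor:] + controls:
        for cond in set(cond_of_col):
            true_mean[g][cond] = 0.0

    snr = rng.uniform(5.0, 50.0, size=(n_genes, n_samples))
    if spec.snr_dropout_rate > 0:
        drop = rng.random((n_genes, n_samples)) < spec.snr_dropout_rate
        snr[drop] = rng.uniform(0.2, 1.9, size=int(drop.sum()))

    x = ExpressionMatrix(genes=genes, design=spec.design, values=values, snr=snr)
    truth = SyntheticTruth(
        module_of=module_of,
        true_mean=true_mean,
        planted_correlation=planted_r,
        hub_genes=hub_genes,
        negative_controls=list(controls),
        seed=spec.seed,
    )
    return x, truth


#: Module sizes of the study-scale preset: 13 modules summing to 614 genes,
#: the largest with 138 members.
STUDY_PRESET_SIZES = (138, 70, 65, 60, 55, 50, 45, 40, 35, 25, 15, 10, 6)

#: Dominant functional category per preset module (cycled), echoing the
#: carbohydrate-transport / energy / amino-acid themes of real modules.
_PRESET_DOMINANT_COGS = ("G", "C", "E", "F", "H", "J", "K", "L", "O", "P", "R", "T", "M")


def study_preset(seed: int = 0, n_hubs_per_module: int = 1) -> SyntheticSpec:
    """Study-scale preset: 2322 genes, 33 arrays, 13 planted modules (614
    genes, largest 138), within-module correlation 0.95, 2-log2 mean shifts.

    Each module responds to one condition, cycled over the 11 conditions of
    the design, so the dataset exercises the differential-expression filter
    and the correlation network together.
    """
    design = default_design()
    conditions = design.conditions()
    modules = []
    for k, size in enumerate(STUDY_PRESET_SIZES):
        # one distinct responsive condition per module; the two modules past
        # the 11 conditions are constitutive co-expression clusters (shared
        # factor, no condition response) so that no two modules share a mean
        # pattern — overlapping signatures would correlate across modules
        responsive = (
            frozenset([conditions[k]]) if k < len(conditions) else frozenset()
        )
        modules.append(
            ModuleSpec(
                module_id=f"M{k + 1:02d}",
                size=size,
                responsive_conditions=responsive,
                mean_shift=2.0,
                within_module_correlation=0.95,
                n_hubs=n_hubs_per_module,
            )
        )
    return SyntheticSpec(
        n_genes=COVERED_GENES,
        design=design,
        modules=tuple(modules),
        n_negative_controls=DEFAULT_NEGATIVE_CONTROLS,
        noise_sd=0.25,
        snr_dropout_rate=0.02,
        seed=seed,
    )


def annotations_for(
    spec: SyntheticSpec, truth: SyntheticTruth, seed: int | None = None
) -> list[GeneAnnotation]:
    """Synthetic COG annotations: each module gets a dominant category
    (~40% of members), other assignments are uniform; ~10% of genes
    unannotated; negative controls never annotated."""
    rng = np.random.default_rng(spec.seed + 104729 if seed is None else seed)
    dominant = {
        m.module_id: _PRESET_DOMINANT_COGS[k % len(_PRESET_DOMINANT_COGS)]
        for k, m in enumerate(spec.modules)
    }
    out = []
    for g, mod in truth.module_of.items():
        if g in set(truth.negative_controls):
            out.append(GeneAnnotation(g, cog=None, is_negative_control=True))
            continue
        u = rng.random()
        if u < 0.10:
            cog = None
        elif mod is not None and u < 0.50:
            cog = dominant[mod]
        else:
            cog = COG_LETTERS[rng.integers(len(COG_LETTERS))]
        out.append(GeneAnnotation(g, cog=cog, is_negative_control=False))
    return out


def write_dataset(
    x: ExpressionMatrix,
    truth: SyntheticTruth,
    out_prefix: str | Path,
    annotations: Sequence[GeneAnnotation] | None = None,
) -> dict[str, Path]:
    """Write expression/SNR/design/annotation/truth TSVs under a prefix."""
    out = Path(out_prefix)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / "expression.tsv",
        "snr": out / "snr.tsv",
        "design": out / "design.tsv",
        "truth": out / "truth.tsv",
    }
    write_expression(x, paths["matrix"], snr_path=paths["snr"], design_path=paths["design"])
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        fh.write("gene_id\tmodule_id\n")
        for g in x.genes:
            fh.write(f"{g}\t{truth.module_of[g] or 'NA'}\n")
    if annotations is not None:
        paths["annotation"] = out / "annotation.tsv"
        write_annotations(annotations, paths["annotation"])
    return paths
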