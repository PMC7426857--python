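"""Synthetic multi-plate targeted-transcriptomic screen generator.

Emulates the statistical structure of a RASL-seq-style compound screen run
on knockout (KO) microglia: a small probe panel with housekeeping genes, a
target-gene probe that is silent in KO-derived wells, WT and KO untreated
control wells on every plate, one compound per treated well, per-well
library-size variation, negative-binomial count noise, and ground truth for
every programmed effect so downstream recovery is testable.

The generative model
--------------------
Each probe g has an expected per-read weight w_g (a proportion; WT weights
sum to 1).  A well with library size L and weight vector w yields counts

    count(g) ~ NB(mean = L * w_g, dispersion = alpha)      var = mu + alpha*mu^2

with ``alpha = 0`` degenerating to Poisson, or exactly ``round(L * w_g)``
in noiseless mode.  KO wells shift the programmed signature genes by
``signature_log2fc`` in log2 space (up/down directions chosen to balance
the shifted read budget) and silence the
target probe; the remaining non-housekeeping probes are rescaled by a common
factor so each genotype's weights sum to 1 — the compositional cost of
shifting some transcripts' share of a fixed read budget.  Housekeeping
weights are identical across genotypes by construction.

A compound with rescue fraction rho moves every non-target probe of its KO
well toward the WT expectation in log2 space:

    log2 w_compound = log2 w_KO + rho * (log2 w_WT - log2 w_KO)

so rho = 1 reproduces the WT expectations exactly (except the target probe,
which stays silent: the compounds are transcriptional mimetics, not
target-gene inducers).

Randomness is centralized in one ``numpy.random.default_rng(seed)``; draws
occur in a fixed documented order (panel weights, rescuer assignment and
rescue fractions, toxic/low-read flags, library sizes, cell counts,
counts), so identical configs give byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SimulationConfig", "SimulationConfigError", "SyntheticTruth", "simulate_screen"]

# Gene-symbol pools used to label probes (flavour only; effects are driven
# by flags, never by names).
_TARGET_SYMBOL = "Grn"
_HOUSEKEEPING_SYMBOLS = ["Gapdh", "Actb", "B2m", "Hprt", "Rpl13a", "Tbp", "Ppia", "Pgk1"]
_PANEL_SYMBOLS = [
    "Ctsd", "Ccl3", "Ccl2", "Ccl4", "Csf1r", "Iba1", "Tgfbr1", "Ifngr1",
    "Il16", "Il10ra", "Il1a", "Trem2", "Tmem119", "P2ry12", "C1qa", "Tnf",
    "Il6", "Ctsb", "Ctss", "Lamp1", "Gba", "Hexb", "Cx3cr1", "Olfml3",
    "Sall1", "Mertk", "Itgam", "Cd68", "Tyrobp", "Apoe", "Clec7a", "Axl",
    "Lpl", "Spp1", "Cst7", "Ctsz", "Grn2",
]
_CATEGORIES = ["inflammatory", "lysosomal", "microglial_homeostatic", "other"]

# log2 knockdown applied to the target probe in KO-derived wells; deep
# enough that expected counts are ~0 at realistic library sizes.
_TARGET_LOG2_KNOCKDOWN = 12.0


class SimulationConfigError(ValueError):
    """A SimulationConfig field violates its invariant."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic screen.

    Defaults mirror the screen layout this pipeline targets: four 384-well
    plates, a 42-probe panel with 6 housekeeping probes and one target-gene
    probe, 1,120 compounds (one well each), 11 programmed signature genes
    shifted by one log2 unit between genotypes, and untreated WT/KO control
    wells on every plate.
    """

    n_plates: int = 4
    wells_per_plate: int = 384
    n_compounds: int = 1120
    n_probes: int = 42
    n_housekeeping: int = 6
    n_signature_true: int = 11
    signature_log2fc: float = 1.0
    library_size_mean: float = 300_000.0
    library_size_cv: float = 0.2
    nb_dispersion: float = 0.05
    n_wt_controls_per_plate: int = 16
    n_ko_controls_per_plate: int = 16
    frac_rescuers: float = 0.05
    rescue_fraction_range: tuple[float, float] = (0.7, 1.0)
    frac_toxic: float = 0.05
    frac_lowread: float = 0.02
    seed: int = 0
    # secondary knobs (kept out of the headline layout parameters)
    cell_count_sd: float = 0.1
    toxic_cell_range: tuple[float, float] = (0.05, 0.35)
    lowread_library_range: tuple[float, float] = (10_000.0, 80_000.0)
    noiseless: bool = False

    def validate(self) -> None:
        if self.n_plates < 1:
            raise SimulationConfigError("n_plates must be >= 1")
        if self.n_probes < 3:
            raise SimulationConfigError("n_probes must be >= 3")
        if not 1 <= self.n_housekeeping < self.n_probes:
            raise SimulationConfigError("n_housekeeping must be in [1, n_probes)")
        # one probe is reserved for the target gene
        if not 1 <= self.n_signature_true <= self.n_probes - self.n_housekeeping - 1:
            raise SimulationConfigError(
                "n_signature_true must be in [1, n_probes - n_housekeeping - 1]"
            )
        for name in ("frac_rescuers", "frac_toxic", "frac_lowread"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationConfigError(f"{name} must be in [0, 1]")
        lo, hi = self.rescue_fraction_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise SimulationConfigError("rescue_fraction_range must satisfy 0 <= lo <= hi <= 1")
        if self.library_size_mean <= 0:
            raise SimulationConfigError("library_size_mean must be positive")
        if self.library_size_cv < 0:
            raise SimulationConfigError("library_size_cv must be >= 0")
        if self.nb_dispersion < 0:
            raise SimulationConfigError("nb_dispersion must be >= 0")
        if self.n_wt_controls_per_plate < 1 or self.n_ko_controls_per_plate < 1:
            raise SimulationConfigError("each plate needs >= 1 control well per genotype")
        controls = self.n_wt_controls_per_plate + self.n_ko_controls_per_plate
        per_plate = int(np.ceil(self.n_compounds / self.n_plates))
        if controls + per_plate > self.wells_per_plate:
            raise SimulationConfigError(
                "wells_per_plate too small for controls plus allocated compounds"
            )


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a simulated screen.

    ``compounds`` has one row per compound: rescue_fraction (0 = inert,
    1 = full shift of KO expectations to WT), is_toxic (cell count drawn
    below the 40% filter), is_lowread (library size drawn below the read
    filter), and the plate/well it occupies.  ``genes`` has one row per
    probe: programmed_log2fc (KO minus WT, zero for housekeeping), the
    signature/target flags, and the log2 expected weights per genotype from
    which any expectation can be recomputed.
    """

    compounds: pd.DataFrame
    genes: pd.DataFrame
    config: SimulationConfig = field(repr=False, default_factory=SimulationConfig)

    def expected_weights(self, rho: float) -> pd.Series:
        """Expected probe weights of a KO-derived well rescued by ``rho``."""
        wt = self.genes["wt_log2_weight"].to_numpy()
        ko = self.genes["ko_log2_weight"].to_numpy()
        mixed = ko + rho * (wt - ko)
        mixed[self.genes["is_target"].to_numpy()] = ko[self.genes["is_target"].to_numpy()]
        return pd.Series(np.exp2(mixed), index=self.genes["probe_id"].to_numpy())

    def to_json(self, path: str | Path) -> None:
        payload = {
            "schema_version": 1,
            "config": asdict(self.config),
            "compounds": self.compounds.to_dict(orient="records"),
            "genes": self.genes.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        cfg = payload["config"]
        for key in ("rescue_fraction_range", "toxic_cell_range", "lowread_library_range"):
            cfg[key] = tuple(cfg[key])
        return cls(
            compounds=pd.DataFrame(payload["compounds"]),
            genes=pd.DataFrame(payload["genes"]),
            config=SimulationConfig(**cfg),
        )


def _well_ids(n: int) -> list[str]:
    """Row-major well labels A01, A02, ... over 24-column plate geometry."""
    rows = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    ids = []
    for i in range(n):
        r, c = divmod(i, 24)
        if r >= len(rows):
            raise SimulationConfigError("wells_per_plate exceeds 24-column plate geometry")
        ids.append(f"{rows[r]}{c + 1:02d}")
    return ids


def _build_panel(cfg: SimulationConfig) -> pd.DataFrame:
    """Probe panel with target, housekeeping, signature and filler probes."""
    n_other = cfg.n_probes - cfg.n_housekeeping - 1
    hk = [_HOUSEKEEPING_SYMBOLS[i % len(_HOUSEKEEPING_SYMBOLS)] + ("" if i < len(_HOUSEKEEPING_SYMBOLS) else str(i)) for i in range(cfg.n_housekeeping)]
    others = [
        _PANEL_SYMBOLS[i] if i < len(_PANEL_SYMBOLS) else f"Gene{i:03d}"
        for i in range(n_other)
    ]
    symbols = [_TARGET_SYMBOL] + others + hk
    categories = (
        ["target"]
        + [_CATEGORIES[i % len(_CATEGORIES)] for i in range(n_other)]
        + ["housekeeping"] * cfg.n_housekeeping
    )
    panel = pd.DataFrame(
        {
            "probe_id": symbols,
            "gene_symbol": symbols,
            "category": categories,
            "is_housekeeping": [c == "housekeeping" for c in categories],
        }
    )
    # signature genes are the first n_signature_true non-target, non-HK probes
    is_sig = np.zeros(cfg.n_probes, dtype=bool)
    is_sig[1 : 1 + cfg.n_signature_true] = True
    panel["is_signature_true"] = is_sig
    panel["is_target"] = panel["category"] == "target"
    return panel


def _build_gene_truth(cfg: SimulationConfig, panel: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_probes
    is_hk = panel["is_housekeeping"].to_numpy()
    is_target = panel["is_target"].to_numpy()
    is_sig = panel["is_signature_true"].to_numpy()

    # draw 1: WT base log2 weights (housekeeping probes sit high so their
    # sum is a stable normalization denominator)
    log2_w = rng.normal(0.0, 1.0, size=n)
    log2_w[is_hk] = rng.normal(3.0, 0.5, size=is_hk.sum())
    w = np.exp2(log2_w)
    w /= w.sum()
    wt_log2 = np.log2(w)

    # signature shift directions: greedy weight balancing keeps the summed
    # read budget of shifted genes nearly conserved, so the compositional
    # rescale below stays close to 1 and non-signature genes remain
    # non-differential as the truth table asserts
    sig_idx = np.flatnonzero(is_sig)
    order = sig_idx[np.argsort(-w[sig_idx])]
    up_gain = 2.0**cfg.signature_log2fc - 1.0
    down_gain = 2.0**-cfg.signature_log2fc - 1.0
    signs = np.zeros(n)
    net = 0.0
    for g in order:
        if abs(net + w[g] * up_gain) <= abs(net + w[g] * down_gain):
            signs[g], net = 1.0, net + w[g] * up_gain
        else:
            signs[g], net = -1.0, net + w[g] * down_gain

    programmed = np.zeros(n)
    programmed[is_sig] = signs[is_sig] * cfg.signature_log2fc

    ko_log2 = wt_log2 + programmed
    ko_log2[is_target] = wt_log2[is_target] - _TARGET_LOG2_KNOCKDOWN

    # compositional closure: rescale filler probes (non-HK, non-signature,
    # non-target) so KO weights also sum to 1 while HK weights stay equal
    # across genotypes
    filler = ~(is_hk | is_sig | is_target)
    ko_w = np.exp2(ko_log2)
    fixed = ko_w[~filler].sum()
    budget = 1.0 - fixed
    filler_sum = ko_w[filler].sum()
    if budget <= 0 or filler_sum <= 0:
        raise SimulationConfigError(
            "signature shifts leave no read budget for non-signature probes"
        )
    ko_w[filler] *= budget / filler_sum
    ko_log2 = np.log2(ko_w)

    truth = panel[["probe_id", "gene_symbol", "category", "is_housekeeping",
                   "is_signature_true", "is_target"]].copy()
    truth["programmed_log2fc"] = programmed
    truth["wt_log2_weight"] = wt_log2
    truth["ko_log2_weight"] = ko_log2
    return truth


def simulate_screen(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Simulate a multi-plate compound screen.

    Returns ``(counts, wells, panel, truth)`` where ``counts`` is a
    wells-by-probes integer DataFrame indexed by ``(plate_id, well_id)``,
    ``wells`` carries per-well metadata on the same index, ``panel``
    describes the probes, and ``truth`` records every programmed effect.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    panel_full = _build_panel(config)
    gene_truth = _build_gene_truth(config, panel_full, rng)
    panel = panel_full[["probe_id", "gene_symbol", "category", "is_housekeeping"]].copy()

    wt_w = np.exp2(gene_truth["wt_log2_weight"].to_numpy())
    ko_w = np.exp2(gene_truth["ko_log2_weight"].to_numpy())
    is_target = gene_truth["is_target"].to_numpy()

    # draw 2: rescuer assignment and rescue fractions
    n_cmp = config.n_compounds
    width = max(4, len(str(n_cmp)))
    compound_ids = np.array([f"C{i + 1:0{width}d}" for i in range(n_cmp)])
    rho = np.zeros(n_cmp)
    n_rescuers = int(round(config.frac_rescuers * n_cmp))
    rescuer_idx = rng.choice(n_cmp, size=n_rescuers, replace=False)
    lo, hi = config.rescue_fraction_range
    rho[rescuer_idx] = rng.uniform(lo, hi, size=n_rescuers)

    # draw 3: toxic and low-read flags (independent per compound)
    is_toxic = rng.random(n_cmp) < config.frac_toxic
    is_lowread = rng.random(n_cmp) < config.frac_lowread

    # plate layout: controls first, then this plate's chunk of compounds
    plate_ids = [f"plate{p + 1}" for p in range(config.n_plates)]
    chunks = np.array_split(np.arange(n_cmp), config.n_plates)
    well_rows: list[dict] = []
    expected_w: list[np.ndarray] = []
    cmp_plate = np.empty(n_cmp, dtype=object)
    cmp_well = np.empty(n_cmp, dtype=object)
    for plate, chunk in zip(plate_ids, chunks):
        n_used = config.n_wt_controls_per_plate + config.n_ko_controls_per_plate + len(chunk)
        ids = _well_ids(n_used)
        cursor = 0
        for _ in range(config.n_wt_controls_per_plate):
            well_rows.append(dict(plate_id=plate, well_id=ids[cursor], genotype="WT",
                                  treatment="untreated", compound_id=""))
            expected_w.append(wt_w)
            cursor += 1
        for _ in range(config.n_ko_controls_per_plate):
            well_rows.append(dict(plate_id=plate, well_id=ids[cursor], genotype="KO",
                                  treatment="untreated", compound_id=""))
            expected_w.append(ko_w)
            cursor += 1
        for ci in chunk:
            well_rows.append(dict(plate_id=plate, well_id=ids[cursor], genotype="KO",
                                  treatment="compound", compound_id=compound_ids[ci]))
            mixed = np.exp2(np.log2(ko_w) + rho[ci] * (np.log2(wt_w) - np.log2(ko_w)))
            mixed[is_target] = ko_w[is_target]
            expected_w.append(mixed)
            cmp_plate[ci], cmp_well[ci] = plate, ids[cursor]
            cursor += 1

    wells = pd.DataFrame(well_rows)
    n_wells = len(wells)
    weights = np.vstack(expected_w)

    # draw 4: library sizes (lognormal with the requested mean and CV);
    # low-read compound wells are overdrawn uniformly below the read filter
    if config.library_size_cv > 0:
        sigma2 = np.log1p(config.library_size_cv**2)
        mu = np.log(config.library_size_mean) - sigma2 / 2.0
        libsize = rng.lognormal(mu, np.sqrt(sigma2), size=n_wells)
    else:
        libsize = np.full(n_wells, config.library_size_mean)
    lowread_compounds = set(compound_ids[is_lowread])
    lowread_mask = wells["compound_id"].isin(lowread_compounds).to_numpy()
    lo_lr, hi_lr = config.lowread_library_range
    libsize[lowread_mask] = rng.uniform(lo_lr, hi_lr, size=int(lowread_mask.sum()))

    # draw 5: cell counts around 1.0; toxic compound wells drawn low
    cell = rng.normal(1.0, config.cell_count_sd, size=n_wells)
    cell = np.clip(cell, 0.01, None)
    toxic_compounds = set(compound_ids[is_toxic])
    toxic_mask = wells["compound_id"].isin(toxic_compounds).to_numpy()
    lo_t, hi_t = config.toxic_cell_range
    cell[toxic_mask] = rng.uniform(lo_t, hi_t, size=int(toxic_mask.sum()))
    wells["cell_count"] = cell

    # draw 6: counts
    mean = weights * libsize[:, None]
    if config.noiseless:
        counts = np.rint(mean).astype(np.int64)
    elif config.nb_dispersion > 0:
        size = 1.0 / config.nb_dispersion
        p = size / (size + mean)
        counts = rng.negative_binomial(size, p).astype(np.int64)
    else:
        counts = rng.poisson(mean).astype(np.int64)

    index = pd.MultiIndex.from_frame(wells[["plate_id", "well_id"]])
    counts_df = pd.DataFrame(counts, index=index, columns=panel["probe_id"].to_list())
    wells = wells.set_index(["plate_id", "well_id"])

    compounds = pd.DataFrame(
        {
            "compound_id": compound_ids,
            "plate_id": cmp_plate,
            "well_id": cmp_well,
            "rescue_fraction": rho,
            "is_toxic": is_toxic,
            "is_lowread": is_lowread,
        }
    )
    truth = SyntheticTruth(compounds=compounds, genes=gene_truth, config=config)
    return counts_df, wells, panel.set_index("probe_id", drop=False), truth
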