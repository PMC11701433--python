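"""Synthetic tissue slides, survival cohorts and expression matrices with
known ground truth.

A slide is a rectangular field (microns) holding three point processes:

* homogeneous Poisson background, one intensity (cells/mm²) per phenotype;
* tumor nests: Poisson-filled discs of PanCK⁺ cells;
* planted lymphoid aggregates: ``n_cells`` cells packed into a disc by
  sequential placement — each new cell lands within ``packing_spacing_um``
  of a randomly chosen existing member and at least 0.45 × that spacing from
  every member — so the aggregate is a single connected component at any
  contact distance ≥ the packing spacing, without lattice artifacts.

Aggregate composition is a fraction map over lymphoid phenotypes converted
to integer counts by largest remainder, with the follicular-dendritic-cell
counts forced consistent with the requested maturity (early: none;
mature_primary: ≥1 CD21⁺CD23⁻, no CD23⁺; mature_secondary: ≥1 CD21⁺CD23⁺).
Marker noise is an independent symmetric flip per cell per marker.

Everything is a pure function of its config (including the seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: canonical marker vocabulary of the simulated panels
MARKERS = ("CD4", "CD8", "CD20", "CD21", "CD23", "DC-LAMP", "GZMB", "PD1",
           "TCF1", "TIM-3", "FoxP3", "CXCR5", "CD68", "CD163", "PanCK", "CALR")

#: phenotype name -> markers set to 1; any bare marker name is also accepted
PHENOTYPE_FLAGS: dict[str, tuple[str, ...]] = {
    "Tumor": ("PanCK",),
    "CD8T": ("CD8",),
    "PD1_CD8T": ("CD8", "PD1"),
    "TCF1_PD1_CD8T": ("CD8", "PD1", "TCF1"),
    "TIM3_PD1_CD8T": ("CD8", "PD1", "TIM-3"),
    "GZMB_CD8T": ("CD8", "GZMB"),
    "CD4T": ("CD4",),
    "TFH": ("CD4", "CXCR5", "PD1"),
    "Treg": ("CD4", "FoxP3"),
    "Bcell": ("CD20",),
    "DC": ("DC-LAMP",),
    "TAM": ("CD68",),
    "M2TAM": ("CD68", "CD163"),
    "FDC21": ("CD21",),
    "FDC21_23": ("CD21", "CD23"),
    "other": (),
}

MATURITY_STATUS = {"early": "eTLS", "mature_primary": "mTLS_primary",
                   "mature_secondary": "mTLS_secondary"}


def _flags_for(name: str) -> tuple[str, ...]:
    if name in PHENOTYPE_FLAGS:
        return PHENOTYPE_FLAGS[name]
    if name in MARKERS:
        return (name,)
    raise ValueError(f"unknown phenotype or marker name {name!r}")


@dataclass(frozen=True)
class TLSSpec:
    """One planted lymphoid aggregate."""

    center: tuple[float, float]
    radius_um: float
    n_cells: int
    composition: dict[str, float]
    maturity: str = "early"
    packing_spacing_um: float = 8.0

    def __post_init__(self):
        if self.radius_um <= 0 or self.n_cells <= 0 or self.packing_spacing_um <= 0:
            raise ValueError("radius, cell count and spacing must be positive")
        if self.maturity not in MATURITY_STATUS:
            raise ValueError(f"maturity must be one of {sorted(MATURITY_STATUS)}")
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"composition fractions sum to {total}, not 1")
        if any(f < 0 for f in self.composition.values()):
            raise ValueError("negative composition fraction")
        for name in self.composition:
            _flags_for(name)
        f21 = self.composition.get("FDC21", 0.0)
        f2123 = self.composition.get("FDC21_23", 0.0)
        if self.maturity == "early" and (f21 > 0 or f2123 > 0):
            raise ValueError("early aggregates must contain no CD21+/CD23+ cells")
        if self.maturity == "mature_primary" and (f21 == 0 or f2123 > 0):
            raise ValueError("mature_primary needs FDC21 > 0 and FDC21_23 == 0")
        if self.maturity == "mature_secondary" and f2123 == 0:
            raise ValueError("mature_secondary needs FDC21_23 > 0")


@dataclass(frozen=True)
class SlideConfig:
    """Full recipe for one synthetic slide."""

    field_width_um: float = 2000.0
    field_height_um: float = 2000.0
    background_rates: dict[str, float] = field(default_factory=dict)
    tumor_nests: list[tuple[tuple[float, float], float, float]] = field(default_factory=list)
    tls_specs: list[TLSSpec] = field(default_factory=list)
    marker_flip_rate: float = 0.0
    clear_margin_um: float = 15.0
    seed: int = 0

    def __post_init__(self):
        if self.field_width_um <= 0 or self.field_height_um <= 0:
            raise ValueError("field dimensions must be positive")
        if not 0.0 <= self.marker_flip_rate <= 1.0:
            raise ValueError("marker_flip_rate must be in [0, 1]")
        if self.clear_margin_um < 0:
            raise ValueError("clear_margin_um must be non-negative")
        for name, rate in self.background_rates.items():
            _flags_for(name)
            if rate < 0:
                raise ValueError(f"negative background rate for {name!r}")
        for (cx, cy), r, rate in self.tumor_nests:
            if r <= 0 or rate < 0:
                raise ValueError("nest radius must be positive, rate non-negative")
            self._check_disc(cx, cy, r, "tumor nest")
        for i, spec in enumerate(self.tls_specs):
            self._check_disc(*spec.center, spec.radius_um, f"TLS spec {i}")
        for i in range(len(self.tls_specs)):
            for j in range(i + 1, len(self.tls_specs)):
                a, b = self.tls_specs[i], self.tls_specs[j]
                d = float(np.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1]))
                if d < a.radius_um + b.radius_um:
                    raise ValueError(
                        f"TLS discs {i} and {j} overlap (center distance {d:.1f} μm "
                        f"< {a.radius_um + b.radius_um:.1f} μm): ground truth ambiguous")

    def _check_disc(self, cx, cy, r, what):
        if not (r <= cx <= self.field_width_um - r
                and r <= cy <= self.field_height_um - r):
            raise ValueError(f"{what} disc at ({cx}, {cy}) r={r} extends outside "
                             f"the {self.field_width_um}×{self.field_height_um} μm field")

    @property
    def area_mm2(self) -> float:
        return self.field_width_um * self.field_height_um / 1e6


@dataclass
class TLSTruth:
    """Ground truth for one planted aggregate."""

    tls_id: int
    cell_ids: list[str]
    status: str
    center: tuple[float, float]
    radius_um: float


def _counts_from_fractions(fractions: dict[str, float], n: int,
                           must_have: tuple[str, ...]) -> dict[str, int]:
    """Largest-remainder apportionment of n cells to phenotypes; every
    phenotype in ``must_have`` (positive fraction) gets at least one cell."""
    names = sorted(fractions)
    quotas = np.array([fractions[k] * n for k in names])
    counts = np.floor(quotas).astype(int)
    rem = quotas - counts
    short = n - counts.sum()
    for idx in np.argsort(-rem, kind="stable")[:short]:
        counts[idx] += 1
    out = dict(zip(names, counts.tolist()))
    for name in must_have:
        if fractions.get(name, 0) > 0 and out.get(name, 0) == 0:
            donor = max(out, key=lambda k: (out[k], k != name))
            out[donor] -= 1
            out[name] = 1
    return out


def _place_packed(rng: np.random.Generator, center, radius, n, spacing) -> np.ndarray:
    """Place n cells in a disc: connected at ``spacing`` and spanning the
    disc diameter.

    A skeleton of jittered radial arms (consecutive points < ``spacing``
    apart, outermost point at the disc edge) guarantees that the aggregate's
    Feret diameter reaches the disc diameter; the remaining cells are added
    by sequential anchored placement — each within ``spacing`` of a random
    existing member — under a minimum-separation rejection rule at
    0.45 × spacing. Lattice artifacts are avoided by the jitter and the
    random fill.
    """
    min_sep = 0.45 * spacing
    step = 0.8 * spacing
    pts = np.empty((n, 2))
    pts[0] = center
    k = 1

    arm_len = int(np.ceil(radius / step))
    n_arms = 4
    while n_arms > 2 and 1 + n_arms * arm_len > max(1, int(0.85 * n)):
        n_arms -= 1
    base = rng.uniform(0.0, 2.0 * np.pi)
    for a in range(n_arms):
        if k >= n:
            break
        ang = base + 2.0 * np.pi * a / n_arms
        u = np.array([np.cos(ang), np.sin(ang)])
        prev = pts[0]
        for j in range(1, arm_len + 1):
            if k >= n:
                break
            r = min(j * step, radius - 1e-6)
            target = center + r * u
            placed = False
            for _ in range(40):
                p = target + rng.normal(0.0, 0.15 * spacing, size=2)
                if np.hypot(*(p - center)) > radius:
                    continue
                if np.hypot(*(p - prev)) > 0.95 * spacing:
                    continue
                if (((pts[:k] - p) ** 2).sum(axis=1) < min_sep ** 2).any():
                    continue
                pts[k] = p
                placed = True
                break
            if not placed:
                # unjittered fallback, projected into the disc: the convex
                # projection keeps the hop from prev at most 0.8 x spacing
                p = prev + step * u
                d = np.hypot(*(p - center))
                if d > radius - 1e-6:
                    p = center + (radius - 1e-6) * (p - center) / d
                pts[k] = p
            prev = pts[k]
            k += 1

    attempts = 0
    max_attempts = 500 * n + 10_000
    while k < n:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"cannot pack {n} cells at spacing {spacing} μm into a "
                f"{radius} μm disc; enlarge the disc or the spacing")
        anchor = pts[rng.integers(k)]
        theta = rng.uniform(0.0, 2.0 * np.pi)
        rad = rng.uniform(min_sep, 0.999 * spacing)
        p = anchor + rad * np.array([np.cos(theta), np.sin(theta)])
        if (p[0] - center[0]) ** 2 + (p[1] - center[1]) ** 2 > radius ** 2:
            continue
        d2 = ((pts[:k] - p) ** 2).sum(axis=1)
        if (d2 < min_sep ** 2).any():
            continue
        pts[k] = p
        k += 1
    return pts


def _rows(prefix, xy, flag_lists):
    rows = []
    for i, ((x, y), flags) in enumerate(zip(xy, flag_lists)):
        row = {"cell_id": f"{prefix}-{i:05d}", "x_um": float(x), "y_um": float(y)}
        for m in MARKERS:
            row[m] = 0
        for m in flags:
            row[m] = 1
        rows.append(row)
    return rows


def simulate_slide(config: SlideConfig) -> tuple[pd.DataFrame, list[TLSTruth]]:
    """Generate one slide: (cell table, planted-aggregate ground truth)."""
    rng = np.random.default_rng(config.seed)
    w, h = config.field_width_um, config.field_height_um
    rows: list[dict] = []

    def _outside_tls(xy: np.ndarray) -> np.ndarray:
        # planted aggregates displace other tissue: thin any point within
        # clear_margin of a planted disc so the ground truth stays unambiguous
        keep = np.ones(len(xy), dtype=bool)
        for spec in config.tls_specs:
            d = np.hypot(xy[:, 0] - spec.center[0], xy[:, 1] - spec.center[1])
            keep &= d >= spec.radius_um + config.clear_margin_um
        return xy[keep]

    for name in sorted(config.background_rates):
        rate = config.background_rates[name]
        count = rng.poisson(rate * config.area_mm2)
        xy = _outside_tls(rng.uniform([0, 0], [w, h], size=(count, 2)))
        rows += _rows(f"bg_{name}", xy, [_flags_for(name)] * len(xy))

    for ni, ((cx, cy), r, rate) in enumerate(config.tumor_nests):
        count = rng.poisson(rate * np.pi * r * r / 1e6)
        rad = r * np.sqrt(rng.uniform(size=count))
        theta = rng.uniform(0, 2 * np.pi, size=count)
        xy = _outside_tls(
            np.column_stack([cx + rad * np.cos(theta), cy + rad * np.sin(theta)]))
        rows += _rows(f"nest{ni}", xy, [("PanCK",)] * len(xy))

    truths: list[TLSTruth] = []
    for ti, spec in enumerate(config.tls_specs):
        xy = _place_packed(rng, np.asarray(spec.center, float), spec.radius_um,
                           spec.n_cells, spec.packing_spacing_um)
        counts = _counts_from_fractions(
            spec.composition, spec.n_cells,
            must_have=("FDC21", "FDC21_23", "CD4T", "CD8T", "TFH"))
        labels = np.repeat([k for k in sorted(counts)],
                           [counts[k] for k in sorted(counts)])
        rng.shuffle(labels)
        tls_rows = _rows(f"tls{ti}", xy, [_flags_for(l) for l in labels])
        truths.append(TLSTruth(
            tls_id=ti, cell_ids=[r["cell_id"] for r in tls_rows],
            status=MATURITY_STATUS[spec.maturity],
            center=spec.center, radius_um=spec.radius_um))
        rows += tls_rows

    table = pd.DataFrame(rows, columns=["cell_id", "x_um", "y_um", *MARKERS])
    if len(table) == 0:
        table = pd.DataFrame(columns=["cell_id", "x_um", "y_um", *MARKERS])
    if config.marker_flip_rate > 0 and len(table) > 0:
        vals = table[list(MARKERS)].to_numpy(dtype=np.int64)
        flips = rng.random(vals.shape) < config.marker_flip_rate
        table[list(MARKERS)] = np.where(flips, 1 - vals, vals)
    table.attrs["sample_id"] = f"slide_seed{config.seed}"
    return table, truths


@dataclass(frozen=True)
class CohortConfig:
    """Exponential survival cohort with log-linear covariate effects."""

    n_patients: int = 100
    baseline_hazard: float = 0.05       # events per month
    log_hr_per_covariate: dict[str, float] = field(default_factory=dict)
    censor_rate: float = 0.0            # independent exponential censoring
    covariate_generators: dict[str, dict] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 2:
            raise ValueError("need at least 2 patients")
        if self.baseline_hazard <= 0 or self.censor_rate < 0:
            raise ValueError("baseline_hazard must be > 0 and censor_rate >= 0")


def _draw_covariate(rng, n, params: dict) -> np.ndarray:
    dist = params.get("dist", "bernoulli")
    if dist == "bernoulli":
        return rng.binomial(1, params.get("p", 0.5), size=n).astype(float)
    if dist == "normal":
        return rng.normal(params.get("mean", 0.0), params.get("sd", 1.0), size=n)
    if dist == "uniform":
        return rng.uniform(params.get("lo", 0.0), params.get("hi", 1.0), size=n)
    raise ValueError(f"unknown covariate distribution {dist!r}")


def simulate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw a cohort with exponential event times, hazard
    baseline · exp(Σ covariate · log HR), and independent exponential
    censoring; observed time is the earlier of the two."""
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    covs = {}
    for name in config.log_hr_per_covariate:
        covs.setdefault(name, None)
    for name in config.covariate_generators:
        covs[name] = None
    for name in covs:
        covs[name] = _draw_covariate(rng, n,
                                     config.covariate_generators.get(name, {}))
    lin = np.zeros(n)
    for name, loghr in config.log_hr_per_covariate.items():
        lin += covs[name] * loghr
    hazard = config.baseline_hazard * np.exp(lin)
    if not np.isfinite(hazard).all():
        bad = int(np.flatnonzero(~np.isfinite(hazard))[0])
        raise ValueError(f"non-finite hazard for record {bad}")
    t_event = rng.exponential(1.0 / hazard)
    if config.censor_rate > 0:
        t_cens = rng.exponential(1.0 / config.censor_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    out = pd.DataFrame({"sample_id": [f"pt{i:04d}" for i in range(n)],
                        "time_months": time, "event": event, **covs})
    return out


def simulate_expression(n_per_group: int, signature_genes: list[str],
                        shift: float, n_noise_genes: int = 0,
                        seed: int = 0) -> tuple[pd.DataFrame, pd.Series]:
    """Two-group log-scale expression matrix: signature genes are N(0,1) in
    group A and N(shift,1) in group B; noise genes N(0,1) in both. Returns
    (genes × samples matrix, sample -> group labels)."""
    if n_per_group < 2:
        raise ValueError("need at least 2 samples per group")
    if not np.isfinite(shift):
        raise ValueError("shift must be finite")
    genes = list(signature_genes) + [f"NOISE{i:04d}" for i in range(n_noise_genes)]
    if len(set(genes)) != len(genes):
        dup = next(g for g in genes if genes.count(g) > 1)
        raise ValueError(f"duplicate gene name {dup!r}")
    rng = np.random.default_rng(seed)
    samples = [f"A{i:03d}" for i in range(n_per_group)] + \
              [f"B{i:03d}" for i in range(n_per_group)]
    vals = rng.normal(0.0, 1.0, size=(len(genes), 2 * n_per_group))
    vals[:len(signature_genes), n_per_group:] += shift
    matrix = pd.DataFrame(vals, index=pd.Index(genes, name="gene"), columns=samples)
    labels = pd.Series(["A"] * n_per_group + ["B"] * n_per_group,
                       index=samples, name="group")
    return matrix, labels
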