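"""Synthetic data generators with exact ground truth.

Three generators mirror the three kinds of raw data the quantification
chain consumes:

* ``generate_frame`` renders a 2D culture micrograph — a 1.5 mm × 1.5 mm
  field of ~220 circular somata joined by line-like dendrites — together
  with the true soma positions, dendrite polylines and the true
  cell-connectivity graph.
* ``generate_plate`` draws a plate-assay fluorescence table (well, group,
  value) around known group means.
* ``generate_protein_matrix`` draws a proteinGroups-style protein × sample
  intensity matrix with planted group effects, below-detection
  missingness and contaminant rows.

Everything is deterministic under its seed: identical parameters and seed
produce bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import networkx as nx
import numpy as np
from shapely.geometry import LineString, Point

from .errors import PlacementError, ValidationError

__all__ = [
    "FrameSimParams",
    "Soma",
    "Dendrite",
    "FrameScene",
    "generate_frame",
    "PlateDesign",
    "generate_plate",
    "ProteinSimParams",
    "PlantedTruth",
    "generate_protein_matrix",
    "ROBUSTNESS_NOISE_SD",
]

#: Documented additive Gaussian pixel-noise level (on the 0–255 intensity
#: scale) at which soma detection is required to keep F1 >= 0.95 and the
#: connectivity counts to stay within 5% of truth.
ROBUSTNESS_NOISE_SD = 12.0

INTENSITY_RANGE = (0.0, 255.0)


# ---------------------------------------------------------------------------
# frame simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FrameSimParams:
    """Parameters of the synthetic culture-field generator.

    All geometric parameters are physical (µm or mm); pixel geometry is
    always derived from ``pixel_size_um``.
    """

    field_size_mm: float = 1.5
    pixel_size_um: float = 1.0
    n_cells: int = 220
    soma_radius_um_range: tuple[float, float] = (5.0, 12.0)
    dendrite_width_um_range: tuple[float, float] = (1.5, 3.0)
    synapse_prob: float = 0.12
    distance_cutoff_um: float = 150.0
    clump_fraction: float = 0.0
    stub_fraction: float = 0.05
    stub_length_um_range: tuple[float, float] = (30.0, 80.0)
    midpoint_jitter_um: float = 4.0
    noise_sd: float = 0.0
    background_level: float = 30.0
    foreground_level: float = 200.0
    min_soma_gap_um: float = 8.0
    # clearance must exceed the masking attachment tolerance (5 um), so a
    # stroke passing near a third soma can never be mistaken for attached
    dendrite_clearance_um: float = 8.0
    edge_margin_um: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.field_size_mm <= 0:
            raise ValidationError("field_size_mm must be > 0")
        if self.pixel_size_um <= 0:
            raise ValidationError("pixel_size_um must be > 0")
        if self.n_cells < 0:
            raise ValidationError("n_cells must be >= 0")
        if not 0.0 <= self.synapse_prob <= 1.0:
            raise ValidationError("synapse_prob must lie in [0, 1]")
        if not 0.0 <= self.clump_fraction <= 1.0:
            raise ValidationError("clump_fraction must lie in [0, 1]")
        if not 0.0 <= self.stub_fraction:
            raise ValidationError("stub_fraction must be >= 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        lo, hi = self.soma_radius_um_range
        if not (0 < lo <= hi):
            raise ValidationError("soma_radius_um_range must be 0 < min <= max")
        wlo, whi = self.dendrite_width_um_range
        if not (0 < wlo <= whi):
            raise ValidationError("dendrite_width_um_range must be 0 < min <= max")
        if whi >= 60.0:
            # rendered dendrites must respect the 0.06 mm masking threshold
            raise ValidationError(
                "dendrite_width_um_range max must be < 60 um (masking threshold)"
            )
        if self.background_level >= self.foreground_level:
            raise ValidationError("background_level must be < foreground_level")

    @property
    def pixel_size_mm(self) -> float:
        return self.pixel_size_um / 1000.0

    @property
    def n_pixels(self) -> int:
        return int(round(self.field_size_mm / self.pixel_size_mm))


@dataclass(frozen=True)
class Soma:
    id: int
    x_mm: float
    y_mm: float
    radius_mm: float
    clump_id: Optional[int] = None

    @property
    def center(self) -> np.ndarray:
        return np.array([self.x_mm, self.y_mm])


@dataclass(frozen=True)
class Dendrite:
    id: int
    polyline_mm: np.ndarray  # (k, 2) array of (x, y) points in mm
    width_mm: float
    endpoints: tuple[int, ...]  # one or two soma ids

    @property
    def length_mm(self) -> float:
        d = np.diff(self.polyline_mm, axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())


@dataclass
class FrameScene:
    """A simulated field with its full ground truth.

    ``true_graph`` is an undirected multigraph over soma ids with one edge
    per dendrite joining two distinct somata.  ``soma_mask`` and
    ``dendrite_mask`` are the exact rendered pixel sets (the dendrite mask
    excludes soma-disc pixels) and exist for validation against the
    masking chain.
    """

    somata: list[Soma]
    dendrites: list[Dendrite]
    true_graph: nx.MultiGraph
    image: np.ndarray
    pixel_size_um: float
    soma_mask: np.ndarray = field(repr=False, default=None)
    dendrite_mask: np.ndarray = field(repr=False, default=None)
    params: Optional[FrameSimParams] = None

    def validate(self) -> None:
        ids = {s.id for s in self.somata}
        for d in self.dendrites:
            for e in d.endpoints:
                if e not in ids:
                    raise ValidationError(
                        f"dendrite {d.id} references unknown soma {e}"
                    )
        n_connecting = sum(
            1 for d in self.dendrites
            if len(d.endpoints) == 2 and d.endpoints[0] != d.endpoints[1]
        )
        if self.true_graph.number_of_edges() != n_connecting:
            raise ValidationError("true_graph edge count does not match dendrites")


def _disc_pixels(mask: np.ndarray, cx_mm: float, cy_mm: float,
                 r_mm: float, px_mm: float) -> None:
    """Set pixels whose centers fall within the disc (in-place)."""
    n = mask.shape[0]
    cx = cx_mm / px_mm - 0.5
    cy = cy_mm / px_mm - 0.5
    r = r_mm / px_mm
    r0 = max(0, int(math.floor(cy - r)))
    r1 = min(n - 1, int(math.ceil(cy + r)))
    c0 = max(0, int(math.floor(cx - r)))
    c1 = min(n - 1, int(math.ceil(cx + r)))
    if r0 > r1 or c0 > c1:
        return
    yy, xx = np.ogrid[r0:r1 + 1, c0:c1 + 1]
    mask[r0:r1 + 1, c0:c1 + 1] |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r


def _stroke_pixels(mask: np.ndarray, polyline_mm: np.ndarray,
                   width_mm: float, px_mm: float) -> None:
    """Set pixels within width/2 of the polyline (round caps, in-place)."""
    n = mask.shape[0]
    half = width_mm / 2.0 / px_mm  # in pixels
    pts = polyline_mm / px_mm - 0.5  # pixel-index coordinates (x, y)
    for a, b in zip(pts[:-1], pts[1:]):
        r0 = max(0, int(math.floor(min(a[1], b[1]) - half - 1)))
        r1 = min(n - 1, int(math.ceil(max(a[1], b[1]) + half + 1)))
        c0 = max(0, int(math.floor(min(a[0], b[0]) - half - 1)))
        c1 = min(n - 1, int(math.ceil(max(a[0], b[0]) + half + 1)))
        if r0 > r1 or c0 > c1:
            continue
        yy, xx = np.mgrid[r0:r1 + 1, c0:c1 + 1]
        vx, vy = b[0] - a[0], b[1] - a[1]
        l2 = vx * vx + vy * vy
        if l2 == 0:
            d2 = (xx - a[0]) ** 2 + (yy - a[1]) ** 2
        else:
            t = np.clip(((xx - a[0]) * vx + (yy - a[1]) * vy) / l2, 0.0, 1.0)
            d2 = (xx - (a[0] + t * vx)) ** 2 + (yy - (a[1] + t * vy)) ** 2
        mask[r0:r1 + 1, c0:c1 + 1] |= d2 <= half * half


def _place_somata(params: FrameSimParams, rng: np.random.Generator) -> list[Soma]:
    L = params.field_size_mm
    margin = params.edge_margin_um / 1000.0
    gap = params.min_soma_gap_um / 1000.0
    n_clumped = int(round(params.clump_fraction * params.n_cells))
    n_free = params.n_cells - n_clumped

    centers = np.empty((0, 2))
    radii = np.empty(0)
    somata: list[Soma] = []
    max_tries = 200 * max(n_free, 1)
    tries = 0
    while len(somata) < n_free:
        if tries >= max_tries:
            raise PlacementError(params.n_cells, len(somata))
        tries += 1
        r = rng.uniform(*params.soma_radius_um_range) / 1000.0
        lo, hi = r + margin, L - r - margin
        if lo >= hi:
            raise PlacementError(params.n_cells, len(somata))
        x, y = rng.uniform(lo, hi, size=2)
        if len(somata):
            d = np.hypot(centers[:, 0] - x, centers[:, 1] - y)
            if np.any(d < radii + r + gap):
                continue
        somata.append(Soma(len(somata), x, y, r))
        centers = np.vstack([centers, [x, y]])
        radii = np.append(radii, r)

    # clumped somata overlap a randomly chosen host
    next_clump = 0
    clump_of: dict[int, int] = {}
    placed = 0
    tries = 0
    while placed < n_clumped:
        if tries >= 200 * max(n_clumped, 1):
            raise PlacementError(params.n_cells, len(somata))
        tries += 1
        host = somata[rng.integers(0, n_free)]
        r = rng.uniform(*params.soma_radius_um_range) / 1000.0
        theta = rng.uniform(0, 2 * math.pi)
        dist = rng.uniform(0.4, 0.8) * (host.radius_mm + r)
        x = host.x_mm + dist * math.cos(theta)
        y = host.y_mm + dist * math.sin(theta)
        if not (r + margin <= x <= L - r - margin
                and r + margin <= y <= L - r - margin):
            continue
        # keep clear of every soma except the host
        others = [s for s in somata if s.id != host.id]
        if others:
            oc = np.array([[s.x_mm, s.y_mm] for s in others])
            orr = np.array([s.radius_mm for s in others])
            d = np.hypot(oc[:, 0] - x, oc[:, 1] - y)
            if np.any(d < orr + r + gap):
                continue
        if host.id in clump_of:
            cid = clump_of[host.id]
        else:
            cid = next_clump
            next_clump += 1
            clump_of[host.id] = cid
            somata[host.id] = replace(host, clump_id=cid)
        sid = len(somata)
        somata.append(Soma(sid, x, y, r, clump_id=cid))
        clump_of[sid] = cid
        placed += 1
    return somata


def _min_dist_to_polyline(centers: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Min distance from each point in ``centers`` (m,2) to the polyline."""
    best = np.full(len(centers), np.inf)
    for a, b in zip(poly[:-1], poly[1:]):
        v = b - a
        l2 = float(v @ v)
        if l2 == 0:
            d = np.hypot(*(centers - a).T)
        else:
            t = np.clip((centers - a) @ v / l2, 0.0, 1.0)
            proj = a + t[:, None] * v
            d = np.hypot(centers[:, 0] - proj[:, 0], centers[:, 1] - proj[:, 1])
        best = np.minimum(best, d)
    return best


def _grow_dendrites(params: FrameSimParams, somata: list[Soma],
                    rng: np.random.Generator) -> list[Dendrite]:
    """Connection model: every soma pair within the distance cutoff is a
    candidate; each candidate independently becomes a dendrite with
    probability ``synapse_prob`` provided its stroke stays geometrically
    clear of all other structures (so the rendered image and the ground
    truth always agree)."""
    free = [s for s in somata if s.clump_id is None]
    if not free:
        return []
    centers = np.array([[s.x_mm, s.y_mm] for s in somata])
    radii = np.array([s.radius_mm for s in somata])
    clear = params.dendrite_clearance_um / 1000.0
    cutoff = params.distance_cutoff_um / 1000.0
    jitter = params.midpoint_jitter_um / 1000.0

    candidates = []
    for i in range(len(free)):
        for j in range(i + 1, len(free)):
            a, b = free[i], free[j]
            d = math.hypot(a.x_mm - b.x_mm, a.y_mm - b.y_mm)
            if d <= cutoff:
                candidates.append((a, b))

    dendrites: list[Dendrite] = []
    clipped_geoms: list = []
    widths: list[float] = []

    def try_add(poly: np.ndarray, width_mm: float,
                endpoint_ids: tuple[int, ...]) -> bool:
        line = LineString(poly)
        # clearance from every non-endpoint soma
        others = np.ones(len(somata), dtype=bool)
        for e in endpoint_ids:
            others[e] = False
        if others.any():
            d = _min_dist_to_polyline(centers[others], poly)
            if np.any(d < radii[others] + width_mm / 2 + clear):
                return False
        # clip away the endpoint discs; the free part must be one piece
        blocked = line
        for e in endpoint_ids:
            blocked = blocked.difference(
                Point(centers[e]).buffer(radii[e], quad_segs=16))
        if blocked.is_empty or blocked.geom_type != "LineString":
            return False
        # clearance from every accepted dendrite
        for g, w in zip(clipped_geoms, widths):
            if blocked.distance(g) < (width_mm + w) / 2 + clear:
                return False
        dendrites.append(
            Dendrite(len(dendrites), poly, width_mm, endpoint_ids))
        clipped_geoms.append(blocked)
        widths.append(width_mm)
        return True

    for a, b in candidates:
        if rng.random() >= params.synapse_prob:
            continue
        width = rng.uniform(*params.dendrite_width_um_range) / 1000.0
        p, q = a.center, b.center
        mid = (p + q) / 2.0
        if jitter > 0:
            seg = q - p
            norm = math.hypot(*seg)
            perp = np.array([-seg[1], seg[0]]) / norm if norm > 0 else np.zeros(2)
            mid = mid + perp * rng.uniform(-jitter, jitter)
            poly = np.vstack([p, mid, q])
        else:
            poly = np.vstack([p, q])
        try_add(poly, width, (a.id, b.id))

    # unconnected stubs: one endpoint on a soma, the other free
    n_stubs = int(round(params.stub_fraction * params.n_cells))
    L = params.field_size_mm
    margin = params.edge_margin_um / 1000.0
    for _ in range(n_stubs):
        for _attempt in range(50):
            anchor = free[rng.integers(0, len(free))]
            theta = rng.uniform(0, 2 * math.pi)
            length = rng.uniform(*params.stub_length_um_range) / 1000.0
            width = rng.uniform(*params.dendrite_width_um_range) / 1000.0
            end = anchor.center + length * np.array(
                [math.cos(theta), math.sin(theta)])
            if not (margin <= end[0] <= L - margin
                    and margin <= end[1] <= L - margin):
                continue
            poly = np.vstack([anchor.center, end])
            if try_add(poly, width, (anchor.id,)):
                break
    return dendrites


def generate_frame(params: FrameSimParams) -> FrameScene:
    """Render a synthetic culture field and return it with full truth.

    Raises :class:`PlacementError` if ``n_cells`` non-clumped somata
    cannot be placed without overlap.
    """
    rng = np.random.default_rng(params.seed)
    somata = _place_somata(params, rng)
    dendrites = _grow_dendrites(params, somata, rng)

    n = params.n_pixels
    px_mm = params.pixel_size_mm
    soma_mask = np.zeros((n, n), dtype=bool)
    for s in somata:
        _disc_pixels(soma_mask, s.x_mm, s.y_mm, s.radius_mm, px_mm)
    stroke_mask = np.zeros((n, n), dtype=bool)
    for d in dendrites:
        _stroke_pixels(stroke_mask, d.polyline_mm, d.width_mm, px_mm)
    dendrite_mask = stroke_mask & ~soma_mask

    image = np.full((n, n), params.background_level, dtype=np.float64)
    image[soma_mask | dendrite_mask] = params.foreground_level
    if params.noise_sd > 0:
        image = image + rng.normal(0.0, params.noise_sd, size=image.shape)
        image = np.clip(image, *INTENSITY_RANGE)

    g = nx.MultiGraph()
    g.add_nodes_from(s.id for s in somata)
    for d in dendrites:
        if len(d.endpoints) == 2 and d.endpoints[0] != d.endpoints[1]:
            g.add_edge(d.endpoints[0], d.endpoints[1], key=d.id)

    scene = FrameScene(
        somata=somata,
        dendrites=dendrites,
        true_graph=g,
        image=image,
        pixel_size_um=params.pixel_size_um,
        soma_mask=soma_mask,
        dendrite_mask=dendrite_mask,
        params=params,
    )
    scene.validate()
    return scene


# ---------------------------------------------------------------------------
# plate simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlateDesign:
    """Design of a simulated plate assay.

    ``group_means`` are the true mean signals per arm; ``insulted`` only
    records whether the arm models the 200 µM hydrogen-peroxide insult
    (a label, nothing is simulated differently).
    """

    group_means: dict[str, float]
    wells_per_group: int = 6
    noise_sd: float = 0.0
    insulted: bool = False
    assay_name: str = "assay"
    seed: int = 0

    def __post_init__(self):
        if self.wells_per_group < 2:
            raise ValidationError("wells_per_group must be >= 2 for ANOVA")
        if any(m <= 0 for m in self.group_means.values()):
            raise ValidationError("group_means must be > 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")

    @property
    def groups(self) -> list[str]:
        return list(self.group_means)


def generate_plate(design: PlateDesign):
    """Draw one value per well as group mean + Gaussian noise."""
    from .stats import AssayTable
    import pandas as pd

    rng = np.random.default_rng(design.seed)
    rows = []
    for group, mean in design.group_means.items():
        vals = mean + rng.normal(0.0, design.noise_sd, size=design.wells_per_group)
        for i, v in enumerate(vals):
            rows.append((f"{group}_{i + 1}", group, float(v)))
    df = pd.DataFrame(rows, columns=["well", "group", "value"])
    return AssayTable(df, assay_name=design.assay_name, insulted=design.insulted)


# ---------------------------------------------------------------------------
# protein matrix simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProteinSimParams:
    """Parameters of the protein-intensity simulator.

    Intensities are log-normal: per-protein base means are drawn on the
    log2 scale, group effects of ``spike_log2fc`` are planted in a
    ``spike_fraction`` of non-contaminant proteins, and measurement noise
    of ``within_group_sd`` (log2 units) is added.  Missingness is
    intensity-dependent by default ("mnar": a value goes missing when it
    falls below a detection limit placed at the ``missing_rate`` quantile
    of the log2 intensities, with Gaussian jitter), matching the
    below-detection mechanism that down-shifted imputation assumes; set
    ``missing_mode="mcar"`` for uniform missingness.
    """

    n_proteins: int = 1000
    n_samples_per_group: int = 4
    group_labels: tuple[str, ...] = ("B12", "combo")
    log2_base_mean_range: tuple[float, float] = (21.0, 28.0)
    between_protein_sd: float = 0.5
    within_group_sd: float = 0.25
    spike_fraction: float = 0.05
    spike_log2fc: float = 1.0
    missing_rate: float = 0.1
    missing_mode: str = "mnar"
    mnar_sigma: float = 0.3
    contaminant_fraction: float = 0.05
    decoy_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("spike_fraction", "missing_rate",
                     "contaminant_fraction", "decoy_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.n_samples_per_group < 2:
            raise ValidationError("n_samples_per_group must be >= 2")
        if len(self.group_labels) < 2:
            raise ValidationError("need at least 2 groups")
        if self.missing_mode not in ("mnar", "mcar"):
            raise ValidationError("missing_mode must be 'mnar' or 'mcar'")
        if self.within_group_sd < 0 or self.between_protein_sd < 0:
            raise ValidationError("standard deviations must be >= 0")

    @property
    def n_groups(self) -> int:
        return len(self.group_labels)


@dataclass(frozen=True)
class PlantedTruth:
    """Which proteins carry a true group effect, and how large it is.

    ``true_log2fc`` maps protein id -> log2 fold change of the treatment
    group (the last group label) relative to the reference (the first);
    unspiked proteins are absent (true effect 0).
    """

    spiked_ids: tuple[str, ...]
    true_log2fc: dict[str, float]
    reference_group: str
    treatment_group: str


def generate_protein_matrix(params: ProteinSimParams):
    """Simulate a raw (linear-scale) protein intensity table.

    Returns ``(ProteinTable, PlantedTruth)``.  Exactly
    ``round(n_proteins * spike_fraction)`` proteins are spiked, chosen
    without replacement among non-contaminant, non-decoy rows; each gets
    a ±``spike_log2fc`` shift (random sign) in the treatment (last) group.
    """
    from .proteomics import ProteinTable
    import pandas as pd

    rng = np.random.default_rng(params.seed)
    P = params.n_proteins
    ids = [f"P{i + 1:05d}" for i in range(P)]
    genes = [f"GENE{i + 1}" for i in range(P)]

    n_cont = int(round(params.contaminant_fraction * P))
    n_decoy = int(round(params.decoy_fraction * P))
    flagged = rng.choice(P, size=min(P, n_cont + n_decoy), replace=False)
    is_cont = np.zeros(P, dtype=bool)
    is_decoy = np.zeros(P, dtype=bool)
    is_cont[flagged[:n_cont]] = True
    is_decoy[flagged[n_cont:]] = True

    clean = np.flatnonzero(~(is_cont | is_decoy))
    n_spike = int(round(params.spike_fraction * P))
    if n_spike > len(clean):
        raise ValidationError("spike_fraction too high for the unflagged rows")
    spiked = rng.choice(clean, size=n_spike, replace=False) if n_spike else \
        np.empty(0, dtype=int)
    signs = rng.choice([-1.0, 1.0], size=n_spike)

    base = rng.uniform(*params.log2_base_mean_range, size=P)
    base = base + rng.normal(0.0, params.between_protein_sd, size=P)

    k = params.n_groups
    nspg = params.n_samples_per_group
    effect = np.zeros((P, k))
    effect[spiked, k - 1] = signs * params.spike_log2fc

    log2x = (base[:, None, None]
             + effect[:, :, None]
             + rng.normal(0.0, params.within_group_sd, size=(P, k, nspg)))
    log2x = log2x.reshape(P, k * nspg)

    if params.missing_rate > 0:
        if params.missing_mode == "mcar":
            missing = rng.random(log2x.shape) < params.missing_rate
        else:
            limit = np.quantile(log2x, params.missing_rate)
            missing = (log2x + rng.normal(0.0, params.mnar_sigma,
                                          size=log2x.shape)) < limit
    else:
        missing = np.zeros(log2x.shape, dtype=bool)

    intens = np.power(2.0, log2x)
    intens[missing] = np.nan

    samples = [f"{g}_{i + 1}" for g in params.group_labels for i in range(nspg)]
    intensities = pd.DataFrame(intens, index=ids, columns=samples)
    sample_groups = {s: g for g in params.group_labels
                     for s in [f"{g}_{i + 1}" for i in range(nspg)]}

    table = ProteinTable(
        intensities=intensities,
        sample_groups=sample_groups,
        gene_symbols=pd.Series(genes, index=ids),
        is_contaminant=pd.Series(is_cont, index=ids),
        is_decoy=pd.Series(is_decoy, index=ids),
        state="raw",
    )
    truth = PlantedTruth(
        spiked_ids=tuple(ids[i] for i in spiked),
        true_log2fc={ids[i]: float(s * params.spike_log2fc)
                     for i, s in zip(spiked, signs)},
        reference_group=params.group_labels[0],
        treatment_group=params.group_labels[-1],
    )
    return table, truth
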