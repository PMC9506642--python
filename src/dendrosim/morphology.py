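"""Branched neuron morphologies: SWC I/O, site selection and spatial discretization.

Conventions
-----------
* Lengths and diameters in micrometres, membrane areas in cm**2, axial
  conductances in microsiemens.
* Path distance is measured along the neurite path from the soma centre
  (0 at the soma centre).
* The soma is represented as a single iso-potential compartment, a sphere
  of area equal to the reconstructed somatic surface.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DomainError, StructuralError

REGIONS = ("soma", "axon", "basal", "apical")
_SWC_TYPE_TO_REGION = {1: "soma", 2: "axon", 3: "basal", 4: "apical"}
_REGION_TO_SWC_TYPE = {v: k for k, v in _SWC_TYPE_TO_REGION.items()}


@dataclass
class Section:
    """An unbranched stretch of neurite (or the soma)."""

    id: int
    parent: int  # -1 for the root
    parent_frac: float  # arc-length fraction on the parent where we attach
    region: str
    length: float  # μm
    diam_prox: float  # μm
    diam_dist: float  # μm
    points: np.ndarray | None = None  # optional (k, 4) array: x, y, z, diam

    def diam_at(self, frac: float) -> float:
        """Diameter (μm) at arc-length fraction ``frac`` (linear taper)."""
        return self.diam_prox + (self.diam_dist - self.diam_prox) * frac


@dataclass(frozen=True)
class SiteRef:
    """A point on the tree: section id plus arc-length fraction in [0, 1]."""

    section: int
    frac: float
    path_distance: float  # μm from the soma centre

    def __post_init__(self):
        if not 0.0 <= self.frac <= 1.0:
            raise DomainError(f"site fraction {self.frac} outside [0, 1]")
        if self.path_distance < 0:
            raise DomainError("negative path distance")


class SectionTree:
    """A rooted tree of :class:`Section` objects; the root is the soma."""

    def __init__(self, sections: list[Section]):
        self.sections = sections
        self._by_id = {s.id: s for s in sections}
        self._children: dict[int, list[int]] = {s.id: [] for s in sections}
        self._validate()
        for s in sections:
            if s.parent >= 0:
                self._children[s.parent].append(s.id)
        self._start_dist = self._compute_start_distances()

    # -- validation ------------------------------------------------------
    def _validate(self) -> None:
        roots = [s for s in self.sections if s.parent < 0]
        if len(roots) != 1:
            raise StructuralError(f"expected exactly one root, found {len(roots)}")
        if roots[0].region != "soma":
            raise StructuralError("root section must be the soma")
        for s in self.sections:
            if s.parent >= 0 and s.parent not in self._by_id:
                raise StructuralError(
                    f"section {s.id} references missing parent {s.parent}"
                )
            if s.length <= 0:
                raise StructuralError(f"section {s.id} has non-positive length")
            if s.diam_prox <= 0 or s.diam_dist <= 0:
                raise StructuralError(f"section {s.id} has non-positive diameter")
            if s.region not in REGIONS:
                raise StructuralError(f"section {s.id} has unknown region {s.region!r}")
        # cycle check by walking to the root from every section
        for s in self.sections:
            seen = set()
            cur = s.id
            while cur >= 0:
                if cur in seen:
                    raise StructuralError(f"cycle detected at section {cur}")
                seen.add(cur)
                cur = self._by_id[cur].parent

    def _compute_start_distances(self) -> dict[int, float]:
        """Path distance (μm) from the soma centre to each section's proximal end."""
        start: dict[int, float] = {}
        order = self.topological_order()
        for sid in order:
            s = self._by_id[sid]
            if s.parent < 0:
                start[sid] = 0.0  # soma centre
            else:
                p = self._by_id[s.parent]
                if p.region == "soma":
                    # point-soma convention: neurites start at the soma centre
                    start[sid] = 0.0
                else:
                    start[sid] = start[p.id] + s.parent_frac * p.length
        return start

    # -- queries ---------------------------------------------------------
    @property
    def root(self) -> Section:
        return next(s for s in self.sections if s.parent < 0)

    def section(self, sid: int) -> Section:
        return self._by_id[sid]

    def children(self, sid: int) -> list[int]:
        return self._children[sid]

    def topological_order(self) -> list[int]:
        """Section ids ordered root-first (every parent precedes its children)."""
        by_parent: dict[int, list[int]] = {}
        for s in self.sections:
            by_parent.setdefault(s.parent, []).append(s.id)
        order: list[int] = []
        stack = sorted(by_parent.get(-1, []), reverse=True)
        while stack:
            sid = stack.pop()
            order.append(sid)
            stack.extend(sorted(by_parent.get(sid, []), reverse=True))
        return order

    def start_distance(self, sid: int) -> float:
        return self._start_dist[sid]

    def end_distance(self, sid: int) -> float:
        s = self._by_id[sid]
        return self._start_dist[sid] + (0.0 if s.region == "soma" else s.length)

    def path_distance(self, site: SiteRef) -> float:
        s = self._by_id[site.section]
        if s.region == "soma":
            return 0.0
        return self._start_dist[site.section] + site.frac * s.length

    def site(self, section: int, frac: float) -> SiteRef:
        """Construct a :class:`SiteRef` with its derived path distance."""
        s = self._by_id[section]
        d = 0.0 if s.region == "soma" else self._start_dist[section] + frac * s.length
        return SiteRef(section=section, frac=frac, path_distance=d)

    def region_extent(self, region: str) -> tuple[float, float]:
        ds = [
            (self.start_distance(s.id), self.end_distance(s.id))
            for s in self.sections
            if s.region == region
        ]
        if not ds:
            raise DomainError(f"no sections of region {region!r}")
        return min(d[0] for d in ds), max(d[1] for d in ds)

    def summary(self) -> dict:
        """JSON-compatible morphology summary."""
        out: dict = {"n_sections": len(self.sections), "regions": {}}
        for region in REGIONS:
            secs = [s for s in self.sections if s.region == region]
            if not secs:
                continue
            out["regions"][region] = {
                "n_sections": len(secs),
                "total_length_um": float(sum(s.length for s in secs)),
                "max_path_distance_um": float(
                    max(self.end_distance(s.id) for s in secs)
                ),
            }
        return out


# ---------------------------------------------------------------------------
# SWC I/O
# ---------------------------------------------------------------------------

def read_swc(stream) -> SectionTree:
    """Parse a standard 7-column SWC stream into a :class:`SectionTree`.

    Type codes 1/2/3/4 map to soma/axon/basal/apical; unknown codes are
    mapped to ``basal`` with a warning.  Chains of samples are merged into
    unbranched sections split at branch points and region changes.
    """
    if isinstance(stream, (str, bytes)):
        stream = io.StringIO(stream if isinstance(stream, str) else stream.decode())
    samples: dict[int, tuple] = {}
    order: list[int] = []
    for line in stream:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise StructuralError(f"malformed SWC line: {line!r}")
        sid = int(parts[0])
        stype = int(parts[1])
        x, y, z, r = (float(v) for v in parts[2:6])
        parent = int(parts[6])
        if sid in samples:
            raise StructuralError(f"duplicate sample id {sid}")
        samples[sid] = (stype, x, y, z, r, parent)
        order.append(sid)

    if not samples:
        raise StructuralError("empty SWC stream")
    for sid in order:
        parent = samples[sid][5]
        if parent != -1 and parent not in samples:
            raise StructuralError(f"sample {sid} references missing parent {parent}")
    # cycle detection on raw samples
    for sid in order:
        seen = set()
        cur = sid
        while cur != -1:
            if cur in seen:
                raise StructuralError(f"cycle detected at sample {cur}")
            seen.add(cur)
            cur = samples[cur][5]

    def region_of(stype: int) -> str:
        if stype not in _SWC_TYPE_TO_REGION:
            warnings.warn(f"unknown SWC type code {stype}; mapping to 'basal'")
            return "basal"
        return _SWC_TYPE_TO_REGION[stype]

    children: dict[int, list[int]] = {sid: [] for sid in order}
    roots: list[int] = []
    for sid in order:
        parent = samples[sid][5]
        if parent == -1:
            roots.append(sid)
        else:
            children[parent].append(sid)

    soma_ids = [sid for sid in order if region_of(samples[sid][0]) == "soma"]
    if not soma_ids:
        raise StructuralError("SWC stream contains no soma sample")
    if len(roots) != 1:
        raise StructuralError(f"expected one root sample, found {len(roots)}")
    root_sample = roots[0]
    if region_of(samples[root_sample][0]) != "soma":
        raise StructuralError(f"root sample {root_sample} is not a soma sample")

    # Soma: equivalent sphere. Single sample -> sphere of that radius;
    # multi-sample soma -> sphere matching the frustum surface of the chain.
    if len(soma_ids) == 1:
        soma_diam = 2.0 * samples[soma_ids[0]][4]
    else:
        area = 0.0
        for sid in soma_ids:
            parent = samples[sid][5]
            if parent in soma_ids:
                _, x1, y1, z1, r1, _ = samples[parent]
                _, x2, y2, z2, r2, _ = samples[sid]
                length = math.dist((x1, y1, z1), (x2, y2, z2))
                area += math.pi * (r1 + r2) * math.hypot(length, r2 - r1)
        if area <= 0:
            soma_diam = 2.0 * samples[soma_ids[0]][4]
        else:
            soma_diam = math.sqrt(area / math.pi)
    soma_xyz = np.array(samples[root_sample][1:4])

    sections: list[Section] = []
    soma_sec_id = 0
    sections.append(
        Section(
            id=soma_sec_id,
            parent=-1,
            parent_frac=0.0,
            region="soma",
            length=soma_diam,
            diam_prox=soma_diam,
            diam_dist=soma_diam,
            points=np.array([[*soma_xyz, soma_diam]]),
        )
    )

    # Build neurite sections: start a new section at every sample whose parent
    # is the soma, is a branch point, or has a different region.
    sample_sec: dict[int, int] = {}
    next_id = 1

    def is_soma(sid: int) -> bool:
        return region_of(samples[sid][0]) == "soma"

    starts = []
    for sid in order:
        if is_soma(sid):
            continue
        parent = samples[sid][5]
        if (
            is_soma(parent)
            or len([c for c in children[parent] if not is_soma(c)]) > 1
            or region_of(samples[parent][0]) != region_of(samples[sid][0])
        ):
            starts.append(sid)

    for start in starts:
        region = region_of(samples[start][0])
        chain = [start]
        cur = start
        while True:
            kids = [c for c in children[cur] if not is_soma(c)]
            if len(kids) == 1 and region_of(samples[kids[0]][0]) == region:
                cur = kids[0]
                chain.append(cur)
            else:
                break
        parent_sample = samples[start][5]
        if is_soma(parent_sample):
            parent_sec = soma_sec_id
            prox_xyz = soma_xyz
            prox_r = samples[start][4]  # neurite's own calibre at the soma
        else:
            parent_sec = sample_sec[parent_sample]
            prox_xyz = np.array(samples[parent_sample][1:4])
            prox_r = samples[parent_sample][4]
        pts = [[*prox_xyz, 2.0 * prox_r]]
        length = 0.0
        prev = prox_xyz
        for sid in chain:
            _, x, y, z, r, _ = samples[sid]
            length += math.dist(prev, (x, y, z))
            prev = (x, y, z)
            pts.append([x, y, z, 2.0 * r])
        if length <= 0:
            raise StructuralError(f"zero-length section starting at sample {start}")
        sec = Section(
            id=next_id,
            parent=parent_sec,
            parent_frac=1.0,
            region=region,
            length=length,
            diam_prox=2.0 * prox_r,
            diam_dist=2.0 * samples[chain[-1]][4],
            points=np.array(pts),
        )
        sections.append(sec)
        for sid in chain:
            sample_sec[sid] = next_id
        next_id += 1

    return SectionTree(sections)


def write_swc(tree: SectionTree, stream) -> None:
    """Write a :class:`SectionTree` as standard 7-column SWC.

    Sections without stored 3D points get straight-line coordinates laid out
    deterministically (children fan out from the parent direction), so a
    write/read round trip preserves topology and path distances.
    """
    lines = ["# generated by dendrosim"]
    next_sample = 1
    # soma as a single sample at the origin of its stored point (or 0,0,0)
    soma = tree.root
    if soma.points is not None and len(soma.points):
        sx, sy, sz = soma.points[0][:3]
    else:
        sx = sy = sz = 0.0
    soma_sample = next_sample
    lines.append(
        f"{soma_sample} 1 {sx:.6f} {sy:.6f} {sz:.6f} {soma.diam_prox / 2:.6f} -1"
    )
    next_sample += 1

    # distal sample id per section, for attaching children
    tip_sample: dict[int, int] = {soma.id: soma_sample}
    tip_xyz: dict[int, np.ndarray] = {soma.id: np.array([sx, sy, sz])}
    tip_dir: dict[int, np.ndarray] = {soma.id: np.array([0.0, 1.0, 0.0])}

    for sid in tree.topological_order():
        sec = tree.section(sid)
        if sec.region == "soma":
            continue
        parent_sample = tip_sample[sec.parent]
        if sec.points is not None and len(sec.points) >= 2:
            pts = sec.points[1:]  # first point duplicates the parent sample
            diams = pts[:, 3]
            coords = pts[:, :3]
        else:
            # synthesize a straight line; spread siblings around the parent axis
            base = tip_xyz[sec.parent]
            siblings = tree.children(sec.parent)
            idx = siblings.index(sid)
            angle = (idx - (len(siblings) - 1) / 2.0) * 0.5
            d0 = tip_dir[sec.parent]
            rot = np.array(
                [
                    [math.cos(angle), -math.sin(angle), 0.0],
                    [math.sin(angle), math.cos(angle), 0.0],
                    [0.0, 0.0, 1.0],
                ]
            )
            direction = rot @ d0
            if sec.region == "basal":
                direction = -direction
            n_pts = max(2, int(math.ceil(sec.length / 20.0)) + 1)
            fr = np.linspace(0.0, 1.0, n_pts)[1:]
            coords = base[None, :] + np.outer(fr * sec.length, direction)
            diams = sec.diam_prox + (sec.diam_dist - sec.diam_prox) * fr
            tip_dir[sid] = direction
        stype = _REGION_TO_SWC_TYPE[sec.region]
        prev = parent_sample
        for (x, y, z), d in zip(coords, diams):
            lines.append(
                f"{next_sample} {stype} {x:.6f} {y:.6f} {z:.6f} {d / 2:.6f} {prev}"
            )
            prev = next_sample
            next_sample += 1
        tip_sample[sid] = prev
        tip_xyz[sid] = np.asarray(coords[-1], dtype=float)
        if sid not in tip_dir:
            v = tip_xyz[sid] - tip_xyz[sec.parent]
            n = np.linalg.norm(v)
            tip_dir[sid] = v / n if n > 0 else tip_dir[sec.parent]

    stream.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Site selection
# ---------------------------------------------------------------------------

def select_site(tree: SectionTree, region: str, distance: float) -> SiteRef:
    """Return the point at ``distance`` μm on the thickest candidate section.

    Among all sections of ``region`` whose span contains ``distance``
    (closed interval), the one with the largest local diameter wins; ties
    break toward the lowest section id.
    """
    if region not in REGIONS:
        raise DomainError(f"unknown region {region!r}")
    candidates: list[tuple[float, int, float]] = []  # (-diam, id, frac)
    for sec in tree.sections:
        if sec.region != region or sec.region == "soma":
            continue
        d0, d1 = tree.start_distance(sec.id), tree.end_distance(sec.id)
        if d0 <= distance <= d1:
            frac = 0.0 if d1 == d0 else (distance - d0) / (d1 - d0)
            candidates.append((-sec.diam_at(frac), sec.id, frac))
    if not candidates:
        raise DomainError(f"no {region} section at distance {distance} μm")
    _, sid, frac = min(candidates)
    return SiteRef(section=sid, frac=frac, path_distance=distance)


# ---------------------------------------------------------------------------
# Discretization
# ---------------------------------------------------------------------------

@dataclass
class CompartmentGraph:
    """Discretized tree: one row per compartment, parents before children."""

    parent: np.ndarray  # (n,) int, -1 for the soma/root
    g_axial: np.ndarray  # (n,) μS, conductance to the parent compartment
    area: np.ndarray  # (n,) cm²
    region: np.ndarray  # (n,) int index into REGIONS
    path_dist: np.ndarray  # (n,) μm at the compartment centre
    section_id: np.ndarray  # (n,) int
    frac0: np.ndarray  # (n,) arc-length fraction at the proximal face
    frac1: np.ndarray  # (n,) arc-length fraction at the distal face
    ra_ohm_cm: float

    @property
    def n(self) -> int:
        return len(self.parent)

    def region_name(self, i: int) -> str:
        return REGIONS[self.region[i]]

    def region_mask(self, region: str) -> np.ndarray:
        return self.region == REGIONS.index(region)

    def site_to_comp(self, site: SiteRef) -> int:
        """Map a :class:`SiteRef` to the index of the containing compartment."""
        mask = self.section_id == site.section
        if not mask.any():
            raise DomainError(f"section {site.section} not in graph")
        idx = np.flatnonzero(mask)
        for i in idx:
            if self.frac0[i] <= site.frac <= self.frac1[i]:
                return int(i)
        return int(idx[-1])

    def total_area(self) -> float:
        return float(self.area.sum())


def _frustum_area_cm2(length_um: float, d1_um: float, d2_um: float) -> float:
    r1, r2 = d1_um / 2.0, d2_um / 2.0
    slant = math.hypot(length_um, r2 - r1)
    return math.pi * (r1 + r2) * slant * 1e-8  # μm² → cm²


def _frustum_axial_megaohm(length_um, d1_um, d2_um, ra_ohm_cm) -> float:
    """Axial resistance (MΩ) of a linearly tapering frustum."""
    r1, r2 = d1_um / 2.0, d2_um / 2.0
    # ∫ Ra/(π r(x)²) dx = Ra L / (π r1 r2); units: Ω·cm · μm / μm² = Ω·cm·μm⁻¹
    return ra_ohm_cm * (length_um * 1e-4) / (math.pi * r1 * r2 * 1e-8) * 1e-6


def discretize(
    tree: SectionTree,
    max_seg_length: float = 20.0,
    *,
    ra_ohm_cm: float = 100.0,
    min_segments: int = 1,
) -> CompartmentGraph:
    """Split every section into compartments no longer than ``max_seg_length`` μm.

    Membrane areas come from truncated-cone frusta; the soma becomes a single
    spherical compartment.  Axial conductances combine the half-compartment
    frustum resistances on either side of each connection (the iso-potential
    soma contributes none).
    """
    if max_seg_length <= 0:
        raise ConfigError("max_seg_length must be positive")
    if min_segments < 1:
        raise ConfigError("min_segments must be >= 1")

    parent_l: list[int] = []
    ga_l: list[float] = []
    area_l: list[float] = []
    region_l: list[int] = []
    dist_l: list[float] = []
    secid_l: list[int] = []
    f0_l: list[float] = []
    f1_l: list[float] = []

    soma = tree.root
    # soma sphere: area π d²  (diam taken from diam_prox)
    parent_l.append(-1)
    ga_l.append(0.0)
    area_l.append(math.pi * soma.diam_prox**2 * 1e-8)
    region_l.append(REGIONS.index("soma"))
    dist_l.append(0.0)
    secid_l.append(soma.id)
    f0_l.append(0.0)
    f1_l.append(1.0)

    comp_of_sec_end: dict[int, int] = {soma.id: 0}
    # half-resistance (MΩ) looking proximally from the distal face of a comp
    half_r_distal: dict[int, float] = {0: 0.0}  # soma: iso-potential

    for sid in tree.topological_order():
        sec = tree.section(sid)
        if sec.region == "soma":
            continue
        nseg = max(min_segments, int(math.ceil(sec.length / max_seg_length)))
        seg_len = sec.length / nseg
        start = tree.start_distance(sid)
        prev_comp = comp_of_sec_end[sec.parent]
        prev_half_r = half_r_distal[prev_comp]
        for k in range(nseg):
            f0, f1 = k / nseg, (k + 1) / nseg
            d1, d2 = sec.diam_at(f0), sec.diam_at(f1)
            dmid = sec.diam_at((f0 + f1) / 2.0)
            comp = len(parent_l)
            r_prox = _frustum_axial_megaohm(seg_len / 2, d1, dmid, ra_ohm_cm)
            r_dist = _frustum_axial_megaohm(seg_len / 2, dmid, d2, ra_ohm_cm)
            r_total = prev_half_r + r_prox
            parent_l.append(prev_comp)
            ga_l.append(1.0 / r_total if r_total > 0 else np.inf)
            area_l.append(_frustum_area_cm2(seg_len, d1, d2))
            region_l.append(REGIONS.index(sec.region))
            dist_l.append(start + (f0 + f1) / 2.0 * sec.length)
            secid_l.append(sid)
            f0_l.append(f0)
            f1_l.append(f1)
            half_r_distal[comp] = r_dist
            prev_comp = comp
            prev_half_r = r_dist
        comp_of_sec_end[sid] = prev_comp

    return CompartmentGraph(
        parent=np.asarray(parent_l, dtype=np.int64),
        g_axial=np.asarray(ga_l),
        area=np.asarray(area_l),
        region=np.asarray(region_l, dtype=np.int64),
        path_dist=np.asarray(dist_l),
        section_id=np.asarray(secid_l, dtype=np.int64),
        frac0=np.asarray(f0_l),
        frac1=np.asarray(f1_l),
        ra_ohm_cm=ra_ohm_cm,
    )
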