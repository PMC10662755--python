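"""End-to-end per-islet analysis: graphs -> cycles (both methods) ->
comparison -> morphometry, producing a JSON-serializable AnalysisResult."""

from __future__ import annotations

import numpy as np

from .datamodel import CLASSES, DegenerateInputError, IsletSection
from .geometric import find_geometric_cycles
from .graphs import TauEstimationError, build_class_graph, connected_components
from .homology import max_h1_persistence, significant_cycles_2d, significant_voids_3d
from .io import AnalysisResult
from .morphometry import (
    contains_center,
    estimate_periphery,
    min_distance_to_center,
    min_distance_to_periphery,
)
from .refine import ShorteningConfig, compare_cycles, greedy_shorten, stochastic_shorten
from .stats import characterize

#: direction name -> (structure class, marker class)
DIRECTIONS = {
    "ad_around_b": ("alphadelta", "beta"),
    "b_around_ad": ("beta", "alphadelta"),
}


def _component_in_cycle(components, enclosed_sets) -> bool:
    """Is some NS component fully inside one cycle (every member enclosed)?"""
    for comp in components:
        if not comp["ns"]:
            continue
        if any(comp["members"] <= s for s in enclosed_sets):
            return True
    return False


def analyze_islet(
    islet: IsletSection,
    shell_width: float = 0.5,
    cell_radius: float = 1.0,
    tau_overrides: dict | None = None,
    shorten: str = "greedy",
    shorten_config: ShorteningConfig | None = None,
    edge_threshold_3d: float = 25.0,
    morphometry: bool = True,
) -> AnalysisResult:
    """Run the whole workflow on one islet.

    ``shorten`` is 'none', 'greedy' or 'stochastic' (stochastic includes a
    final greedy pass).  3D islets get PH voids only; the geometric walk and
    periphery morphometry are 2D constructions.
    """
    tau_overrides = tau_overrides or {}
    result = AnalysisResult(islet_id=islet.islet_id, group=islet.group)
    result.characteristics = characterize(islet).__dict__.copy()

    graphs: dict[str, object | None] = {}
    for cls in CLASSES:
        try:
            graphs[cls] = build_class_graph(
                islet,
                cls,
                shell_width=shell_width,
                cell_radius=cell_radius,
                tau_override=tau_overrides.get(cls),
            )
        except (TauEstimationError, DegenerateInputError):
            graphs[cls] = None
    result.tau = {
        cls: (graphs[cls].tau if graphs[cls] is not None else None) for cls in CLASSES
    }

    if islet.dim == 3:
        for direction, (structure, marker) in DIRECTIONS.items():
            s_ids, s_coords = islet.class_arrays(structure)
            m_ids, m_coords = islet.class_arrays(marker)
            voids = significant_voids_3d(
                s_ids,
                {i: c for i, c in zip(s_ids, s_coords)},
                m_ids,
                m_coords,
                edge_threshold=edge_threshold_3d,
            )
            result.directions[direction] = {
                "ph_boundaries": [
                    {
                        "triangles": sorted(map(list, b.simplices)),
                        "enclosed": sorted(b.enclosed),
                        "n_simplices": b.edge_count,
                    }
                    for b in voids
                ],
            }
        return result

    for cls in CLASSES:
        _, coords = islet.class_arrays(cls)
        result.max_persistence[cls] = max_h1_persistence(coords)

    periphery = None
    if morphometry and all(result.tau[c] is not None for c in CLASSES):
        try:
            all_coords = np.asarray([c.coords for c in islet.cells], dtype=float)
            periphery = estimate_periphery(
                all_coords, result.tau["beta"], result.tau["alphadelta"]
            )
        except DegenerateInputError:
            periphery = None
    if periphery is not None:
        result.morphometry = {
            "islet_area": periphery.area,
            "shrink_factor": periphery.shrink_factor_used,
            "center": [float(x) for x in periphery.centroid],
            "cycles": [],
        }

    for direction, (structure, marker) in DIRECTIONS.items():
        rec: dict = {
            "geometric_cycles": [],
            "ph_boundaries": [],
            "comparisons": [],
            "ns_in_geometric_cycle": False,
            "ns_in_ph_cycle": False,
        }
        result.directions[direction] = rec
        sgraph = graphs[structure]
        mgraph = graphs[marker]
        if sgraph is None:
            continue
        m_ids, m_coords = islet.class_arrays(marker)

        geo, _classes, pg = find_geometric_cycles(sgraph, m_ids, m_coords)
        rec["geometric_cycles"] = [
            {
                "walk": list(gc.walk),
                "enclosed": sorted(gc.enclosed),
                "component_id": gc.component_id,
                "dummy_vertices": {
                    str(v): [sorted(e) for e in prov]
                    for v, prov in gc.dummy_provenance.items()
                },
            }
            for gc in geo
        ]

        ph = significant_cycles_2d(
            sgraph.ids, sgraph.coords, sgraph.edges, m_ids, m_coords
        )
        if shorten == "stochastic":
            ph = stochastic_shorten(sgraph, m_ids, m_coords, ph, shorten_config)
        if shorten in ("greedy", "stochastic"):
            ph = [greedy_shorten(b, sgraph, m_ids, m_coords) for b in ph]
        rec["ph_boundaries"] = [
            {
                "edges": sorted(map(list, b.simplices)),
                "enclosed": sorted(b.enclosed),
                "n_edges": b.edge_count,
            }
            for b in ph
        ]

        rec["comparisons"] = [
            vars(c) for c in compare_cycles(geo, ph, sgraph.coords, sgraph.tau)
        ]

        if mgraph is not None:
            comps = connected_components(mgraph)
            rec["ns_in_geometric_cycle"] = _component_in_cycle(
                comps, [gc.enclosed for gc in geo]
            )
            rec["ns_in_ph_cycle"] = _component_in_cycle(
                comps, [b.enclosed for b in ph]
            )

        if periphery is not None:
            for gi, gc in enumerate(geo):
                poly = gc.polygon(pg.coords)
                result.morphometry["cycles"].append(
                    {
                        "direction": direction,
                        "cycle_index": gi,
                        "dist_periphery": min_distance_to_periphery(poly, periphery),
                        "dist_center": min_distance_to_center(poly, periphery.centroid),
                        "contains_center": contains_center(poly, periphery.centroid),
                    }
                )
    return result


def islet_summary_record(result: AnalysisResult) -> dict:
    """Flatten an AnalysisResult into the record cohort_summary consumes."""
    return {
        "group": result.group,
        "beta_fraction": result.characteristics["beta_fraction"],
        "log_total": result.characteristics["log_total"],
        "n_alpha": result.characteristics["n_alpha"],
        "n_delta": result.characteristics["n_delta"],
        "ns_in_cycle": {
            d: rec.get("ns_in_geometric_cycle", False)
            for d, rec in result.directions.items()
        },
        "ns_in_ph_cycle": {
            d: rec.get("ns_in_ph_cycle", False)
            for d, rec in result.directions.items()
        },
        "max_persistence": dict(result.max_persistence),
    }


def analyze_cohort(islets: list[IsletSection], **kwargs) -> list[AnalysisResult]:
    return [analyze_islet(islet, **kwargs) for islet in islets]
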