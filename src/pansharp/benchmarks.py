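"""Published quality-index benchmarks for WorldView-2 ecosystem scenes.

Reference values of the six fusion quality indices obtained by four
pansharpening algorithms on 512 x 512 WorldView-2 scenes of three Canary
Islands ecosystems (a heterogeneous shrubland, a shallow-water coastal
area and a mixed urban/lagoon/dune area).  They serve as worked examples
for the Borda ranking machinery and as regression anchors: the printed
rank columns of the source study are recomputable from these values.
"""

from __future__ import annotations

from .ranking import IndexTable

__all__ = ["WV2_BENCHMARKS", "benchmark_table", "PUBLISHED_RANK_COLUMNS"]

#: index values per ecosystem and algorithm:
#: sam [degrees], ergas_spectral, ergas_spatial, fc, zhou, q.
WV2_BENCHMARKS: dict[str, dict[str, dict[str, float]]] = {
    "shrubland": {
        "fihs":        {"sam": 3.78, "ergas_spectral": 1.68, "ergas_spatial": 0.89,
                        "fc": 0.84, "zhou": 0.72, "q": 0.90},
        "hcs":         {"sam": 3.52, "ergas_spectral": 0.39, "ergas_spatial": 0.91,
                        "fc": 0.77, "zhou": 0.67, "q": 0.93},
        "mtf_glp_hpm": {"sam": 3.87, "ergas_spectral": 0.33, "ergas_spatial": 0.89,
                        "fc": 0.81, "zhou": 0.71, "q": 0.92},
        "wat_frac":    {"sam": 4.19, "ergas_spectral": 1.44, "ergas_spatial": 0.82,
                        "fc": 0.86, "zhou": 0.89, "q": 0.90},
    },
    "coastal": {
        "fihs":        {"sam": 1.77, "ergas_spectral": 2.91, "ergas_spatial": 2.36,
                        "fc": 0.85, "zhou": 0.83, "q": 0.98},
        "hcs":         {"sam": 1.81, "ergas_spectral": 1.73, "ergas_spatial": 2.64,
                        "fc": 0.64, "zhou": 0.71, "q": 0.98},
        "mtf_glp_hpm": {"sam": 1.64, "ergas_spectral": 1.22, "ergas_spatial": 2.61,
                        "fc": 0.72, "zhou": 0.73, "q": 0.98},
        "wat_frac":    {"sam": 1.93, "ergas_spectral": 2.63, "ergas_spatial": 2.54,
                        "fc": 0.78, "zhou": 0.88, "q": 0.98},
    },
    "mixed": {
        "fihs":        {"sam": 7.11, "ergas_spectral": 2.98, "ergas_spatial": 2.08,
                        "fc": 0.89, "zhou": 0.73, "q": 0.93},
        "hcs":         {"sam": 5.66, "ergas_spectral": 1.73, "ergas_spatial": 2.23,
                        "fc": 0.80, "zhou": 0.61, "q": 0.96},
        "mtf_glp_hpm": {"sam": 5.62, "ergas_spectral": 1.72, "ergas_spatial": 2.23,
                        "fc": 0.81, "zhou": 0.61, "q": 0.96},
        "wat_frac":    {"sam": 6.88, "ergas_spectral": 2.85, "ergas_spatial": 2.05,
                        "fc": 0.93, "zhou": 0.98, "q": 0.95},
    },
}

#: The published Borda rank columns that are arithmetically consistent
#: with a single points scheme (points N..1, spectral = [SAM, spectral
#: ERGAS], spatial = [FC, Zhou]).  The published spectral column for the
#: coastal scene and the tied spatial/global columns resolved with mixed
#: tie rules are not reproducible and are deliberately absent.
PUBLISHED_RANK_COLUMNS: dict[tuple[str, str], dict[str, float]] = {
    ("shrubland", "spectral"): {"fihs": 4, "hcs": 7, "mtf_glp_hpm": 6, "wat_frac": 3},
    ("mixed", "spectral"): {"fihs": 2, "hcs": 6, "mtf_glp_hpm": 8, "wat_frac": 4},
    ("shrubland", "spatial"): {"fihs": 6, "hcs": 2, "mtf_glp_hpm": 4, "wat_frac": 8},
    ("coastal", "spatial"): {"fihs": 7, "hcs": 2, "mtf_glp_hpm": 4, "wat_frac": 7},
}


def benchmark_table(ecosystem: str) -> IndexTable:
    """The published index values for one ecosystem as an
    :class:`~pansharp.ranking.IndexTable`."""
    if ecosystem not in WV2_BENCHMARKS:
        raise KeyError(f"unknown ecosystem {ecosystem!r}; "
                       f"expected one of {sorted(WV2_BENCHMARKS)}")
    return IndexTable({alg: dict(vals)
                       for alg, vals in WV2_BENCHMARKS[ecosystem].items()})
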