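"""Frame-parallel segmentation/extraction driver.

Each (well, frame) is an independent job: load the marker planes, segment,
and extract features.  Jobs are dispatched to a thread pool of ``workers``
threads (the heavy lifting happens in numpy/scipy, which release the GIL);
completed results are collected and written to the HDF5 store by a single
writer in sorted (well, frame) order, so the final store is bit-identical
for any worker count.  A failing frame is logged, recorded under
``/meta/failed``, and skipped without aborting the run.
"""

from __future__ import annotations

import logging
import time
from concurrent.futures import ThreadPoolExecutor
from pathlib import Path

from .config import ConfigError, RunConfig
from .containers import ChannelStack, FeatureTable, concat_tables
from .features import FeatureConfig, enumerate_features, extract_features, render_name
from .io import ResultStore, read_image
from .segmentation import SegmentationResult, segment_frame

logger = logging.getLogger(__name__)


def load_stack(config: RunConfig, well: str, frame: int) -> ChannelStack:
    planes = {
        marker: read_image(config.image_path(well, frame, marker),
                           marker, well, frame)
        for marker in config.markers
    }
    return ChannelStack(planes, well, frame)


def _process_frame(
    config: RunConfig, well: str, frame: int
) -> tuple[SegmentationResult, FeatureTable | None]:
    t0 = time.perf_counter()
    stack = load_stack(config, well, frame)
    seg = segment_frame(stack, config.segmentation)
    table = None
    if config.features:
        table = extract_features(
            seg, stack, FeatureConfig.from_dict(config.features),
            **config.region_widths,
        )
    logger.info("well=%s frame=%d stage=segment+extract cells=%d duration=%.3fs",
                well, frame, seg.n_cells, time.perf_counter() - t0)
    return seg, table


def run_segment_extract(config: RunConfig) -> Path:
    """Segment and extract every discovered frame; returns the store path."""
    jobs = config.discover_frames()
    logger.info("discovered %d frames across %d wells",
                len(jobs), len({w for w, _ in jobs}))

    results: dict[tuple[str, int], tuple[SegmentationResult, FeatureTable | None]] = {}
    failures: dict[tuple[str, int], str] = {}

    def work(job: tuple[str, int]):
        well, frame = job
        try:
            return job, _process_frame(config, well, frame), None
        except Exception as exc:  # noqa: BLE001 - a bad frame must not abort the run
            logger.error("well=%s frame=%d failed: %s", well, frame, exc)
            return job, None, f"{type(exc).__name__}: {exc}"

    if config.workers == 1:
        outcomes = map(work, jobs)
    else:
        with ThreadPoolExecutor(max_workers=config.workers) as pool:
            outcomes = list(pool.map(work, jobs))
    for job, result, err in outcomes:
        if err is None:
            results[job] = result
        else:
            failures[job] = err

    with ResultStore(config.store, "w") as store:
        store.set_meta(config.markers, config.to_yaml_text())
        tables = []
        for job in sorted(results):
            seg, table = results[job]
            store.add_masks(job[0], job[1], seg.nuclei, seg.cells)
            if table is not None:
                tables.append(table)
        if tables:
            store.set_features(concat_tables(tables))
        elif config.features:
            # no frame succeeded but features were requested: store the
            # empty table with its full header for schema stability
            specs = enumerate_features(FeatureConfig.from_dict(config.features))
            names = [render_name(s) for s in specs]
            import numpy as np
            import pandas as pd

            from .containers import CELL_INDEX_COLUMNS
            empty_cells = pd.DataFrame(
                {c: pd.Series(dtype=("float" if "centroid" in c else "object"))
                 for c in CELL_INDEX_COLUMNS}
            )
            store.set_features(
                FeatureTable(np.empty((0, len(names))), names, empty_cells)
            )
        for (well, frame), msg in sorted(failures.items()):
            store.record_failed(well, frame, msg)
    if not results and failures:
        raise ConfigError("every discovered frame failed; see the log")
    return config.store
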