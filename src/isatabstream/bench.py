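"""Scalability measurement harness: CPU time and peak memory vs. row count.

Protocol: before any measurement, a warm-up writes a batch of wide
(real-world-like) rows to a discarding sink; garbage collection is then
forced and a memory baseline captured.  Each measurement writes n study rows
and n assay rows to discarding sinks, recording process CPU time and the
peak traced allocation minus the baseline — so the numbers reflect the
memory consumed by the table content being written, not the interpreter and
library periphery.  Absolute values are hardware- and runtime-specific;
conclusions should be drawn from ratios (e.g. peak memory at 10^5 rows vs.
10^3 rows), which is also how the test suite asserts them.

Memory is tracked with :mod:`tracemalloc` (Python-level allocations), the
closest analogue of measuring the writing process's own consumption.
"""

from __future__ import annotations

import csv
import gc
import time
import tracemalloc
from dataclasses import asdict, dataclass, fields
from typing import Iterable, Sequence, Union

from .errors import InvalidArgumentError
from .fixtures import REAL_WORLD_LIKE, ComplexityLevel, gen_rows
from .streaming import NullSink, WriteStats, open_table, resolve_sink

__all__ = ["MeasurementRecord", "run_benchmark", "write_measurements", "write_level"]

LIBRARY_LABEL = "isatab-stream"


@dataclass(frozen=True)
class MeasurementRecord:
    """One benchmark observation (peak memory is baseline-subtracted)."""

    library_label: str
    complexity: str
    n_rows: int
    rep: int
    cpu_seconds: float
    peak_memory_bytes: int

    def __post_init__(self) -> None:
        if self.n_rows < 1:
            raise InvalidArgumentError(f"n_rows must be >= 1, got {self.n_rows}")
        if self.rep < 1:
            raise InvalidArgumentError(f"rep must be >= 1, got {self.rep}")
        if self.cpu_seconds < 0 or self.peak_memory_bytes < 0:
            raise InvalidArgumentError("measurements must be non-negative")


def write_level(level: ComplexityLevel, n: int, study_sink, assay_sink) -> tuple[WriteStats, WriteStats]:
    """Stream n study rows and n assay rows of ``level`` to the two sinks."""
    study_stream = open_table(study_sink)
    assay_stream = open_table(assay_sink)
    for study_row, assay_row in gen_rows(level, n):
        study_stream.write_row(study_row)
        assay_stream.write_row(assay_row)
    return study_stream.finish(), assay_stream.finish()


def run_benchmark(
    levels: Sequence[ComplexityLevel],
    row_counts: Sequence[int],
    reps: int = 5,
    warmup_rows: int = 100,
    library_label: str = LIBRARY_LABEL,
    trace_memory: bool = True,
) -> list[MeasurementRecord]:
    """Measure CPU time and baseline-subtracted peak memory for each (level, n, rep).

    ``row_counts`` must be non-empty and ascending.  Records are returned in
    execution order.  Allocation tracing itself costs CPU time, so CPU-focused
    runs can pass ``trace_memory=False`` (peak memory is then reported as 0);
    memory and CPU are best measured in separate runs.
    """
    if not row_counts:
        raise InvalidArgumentError("row_counts must be non-empty")
    if list(row_counts) != sorted(row_counts):
        raise InvalidArgumentError("row_counts must be ascending")

    started_tracing = trace_memory and not tracemalloc.is_tracing()
    if started_tracing:
        tracemalloc.start()
    try:
        if warmup_rows > 0:
            write_level(REAL_WORLD_LIKE, warmup_rows, NullSink(), NullSink())
        gc.collect()
        baseline = tracemalloc.get_traced_memory()[0] if trace_memory else 0

        records: list[MeasurementRecord] = []
        for level in levels:
            for n in row_counts:
                for rep in range(1, reps + 1):
                    gc.collect()
                    if trace_memory:
                        tracemalloc.reset_peak()
                    cpu_start = time.process_time()
                    write_level(level, n, NullSink(), NullSink())
                    cpu = time.process_time() - cpu_start
                    peak = tracemalloc.get_traced_memory()[1] if trace_memory else 0
                    records.append(
                        MeasurementRecord(
                            library_label=library_label,
                            complexity=level.name,
                            n_rows=n,
                            rep=rep,
                            cpu_seconds=cpu,
                            peak_memory_bytes=max(0, peak - baseline),
                        )
                    )
        return records
    finally:
        if started_tracing:
            tracemalloc.stop()


def write_measurements(records: Iterable[MeasurementRecord], sink: Union[str, object]) -> WriteStats:
    """Write records as CSV (header + one line per record) to a path or sink."""
    handle, owns = resolve_sink(sink)
    column_names = [f.name for f in fields(MeasurementRecord)]
    lines = 0
    nbytes = 0

    class _Counting:
        def write(self, text: str) -> int:
            nonlocal nbytes
            handle.write(text)
            nbytes += len(text.encode("utf-8"))
            return len(text)

    try:
        writer = csv.DictWriter(_Counting(), fieldnames=column_names, lineterminator="\n")
        writer.writeheader()
        lines += 1
        for record in records:
            writer.writerow(asdict(record))
            lines += 1
        flush = getattr(handle, "flush", None)
        if flush is not None:
            flush()
    finally:
        if owns:
            handle.close()
    return WriteStats(rows_written=lines, bytes_written=nbytes)
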