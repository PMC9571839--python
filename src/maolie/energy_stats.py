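"""Block statistics for ligand--environment interaction-energy time series.

An LIE estimate is built from MD averages of the van der Waals and
electrostatic interaction energy between a ligand and its environment,
sampled in two states: *bound* (solvated protein active site) and *free*
(ligand alone in water).  Because successive MD samples are strongly
autocorrelated, fluctuation statistics are computed by block averaging:
the series is split into contiguous blocks (ten, matching a production
protocol of ten consecutive simulation segments), and the spread of the
block means is reported as the uncertainty of the state average.

The module also defines the on-disk TSV dialect for energy series and the
per-compound summary container that mirrors one row of the published
interaction-energy table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .errors import FormatError, InvalidInputError
from .util import round_half_away

logger = logging.getLogger(__name__)

STATES = ("bound", "free")
COMPONENTS = ("vdw", "el")

#: Number of contiguous blocks used for fluctuation estimates by default.
DEFAULT_N_BLOCKS = 10


class MeanSD(NamedTuple):
    """A mean with its block-average standard deviation, both in kcal/mol."""

    mean: float
    sd: float


@dataclass(frozen=True)
class EnergyTimeSeries:
    """One ligand--environment interaction-energy component over an MD run.

    Parameters
    ----------
    compound_id : int
        Compound label (1-11 for the packaged set; any positive id accepted).
    state : {"bound", "free"}
        Ligand in the solvated protein site, or alone in water.
    component : {"vdw", "el"}
        van der Waals or electrostatic interaction energy.
    values : ndarray
        Energies in kcal/mol, one per sampling step.
    sampling_interval_ps : float
        Time between successive samples, in ps.
    """

    compound_id: int
    state: str
    component: str
    values: np.ndarray
    sampling_interval_ps: float = 1.0

    def __post_init__(self):
        if self.state not in STATES:
            raise InvalidInputError(f"state must be one of {STATES}, got {self.state!r}")
        if self.component not in COMPONENTS:
            raise InvalidInputError(
                f"component must be one of {COMPONENTS}, got {self.component!r}"
            )
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size == 0:
            raise InvalidInputError("values must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(values)):
            raise InvalidInputError("values must all be finite")
        if not self.sampling_interval_ps > 0:
            raise InvalidInputError("sampling_interval_ps must be positive")
        object.__setattr__(self, "values", values)

    @property
    def key(self) -> tuple[str, str]:
        return (self.state, self.component)


@dataclass(frozen=True)
class BlockSummary:
    """Mean and block-average fluctuation of one energy series."""

    n_blocks: int
    block_means: np.ndarray
    mean: float
    sd: float


@dataclass(frozen=True)
class InteractionEnergySummary:
    """Per-compound bound/free energy decomposition (one published-table row).

    ``delta_vdw`` and ``delta_el`` are bound-minus-free differences; their SDs
    combine bound and free fluctuations in quadrature when computed from time
    series, or are stored verbatim when transcribed from a printed table.
    """

    compound_id: int
    charged: bool
    vdw_bound: MeanSD
    vdw_free: MeanSD
    el_bound: MeanSD
    el_free: MeanSD
    delta_vdw: MeanSD
    delta_el: MeanSD


GROUP_FIELDS = ("vdw_bound", "vdw_free", "el_bound", "el_free", "delta_vdw", "delta_el")


def block_statistics(series: EnergyTimeSeries, n_blocks: int = DEFAULT_N_BLOCKS) -> BlockSummary:
    """Split ``series`` into contiguous equal blocks and summarise block means.

    The mean is the arithmetic mean of the block means (equal to the plain
    mean of all retained samples), and the SD is the sample standard deviation
    (divisor ``n_blocks - 1``) of the block means.  Trailing samples that do
    not fill a complete block are discarded with a warning.
    """
    if n_blocks < 2:
        raise InvalidInputError(f"need at least 2 blocks, got {n_blocks}")
    n = series.values.size
    if n < n_blocks:
        raise InvalidInputError(
            f"series has {n} values but {n_blocks} blocks were requested"
        )
    block_len = n // n_blocks
    n_used = block_len * n_blocks
    if n_used != n:
        logger.warning(
            "discarding %d trailing samples not filling a block (series length %d, %d blocks)",
            n - n_used,
            n,
            n_blocks,
        )
    block_means = series.values[:n_used].reshape(n_blocks, block_len).mean(axis=1)
    return BlockSummary(
        n_blocks=n_blocks,
        block_means=block_means,
        mean=float(block_means.mean()),
        sd=float(block_means.std(ddof=1)),
    )


def summarize_compound(
    series: Iterable[EnergyTimeSeries],
    n_blocks: int = DEFAULT_N_BLOCKS,
    charged: bool = False,
) -> InteractionEnergySummary:
    """Assemble the four-state energy decomposition for one compound.

    ``series`` must contain exactly the four (state, component) combinations
    for a single compound.  Difference columns are computed from the unrounded
    means, with SDs combined in quadrature.
    """
    by_key: dict[tuple[str, str], EnergyTimeSeries] = {}
    compound_ids = set()
    for s in series:
        if s.key in by_key:
            raise InvalidInputError(f"duplicate series for (state, component) {s.key}")
        by_key[s.key] = s
        compound_ids.add(s.compound_id)
    expected = {(st, c) for st in STATES for c in COMPONENTS}
    missing = expected - set(by_key)
    if missing:
        raise InvalidInputError(f"missing series for (state, component) pairs: {sorted(missing)}")
    if len(compound_ids) != 1:
        raise InvalidInputError(f"series mix compound ids: {sorted(compound_ids)}")
    (compound_id,) = compound_ids

    stats = {key: block_statistics(s, n_blocks) for key, s in by_key.items()}

    def ms(state: str, comp: str) -> MeanSD:
        b = stats[(state, comp)]
        return MeanSD(b.mean, b.sd)

    vdw_b, vdw_f = ms("bound", "vdw"), ms("free", "vdw")
    el_b, el_f = ms("bound", "el"), ms("free", "el")
    return InteractionEnergySummary(
        compound_id=compound_id,
        charged=charged,
        vdw_bound=vdw_b,
        vdw_free=vdw_f,
        el_bound=el_b,
        el_free=el_f,
        delta_vdw=MeanSD(vdw_b.mean - vdw_f.mean, float(np.hypot(vdw_b.sd, vdw_f.sd))),
        delta_el=MeanSD(el_b.mean - el_f.mean, float(np.hypot(el_b.sd, el_f.sd))),
    )


def summary_from_table_row(
    compound_id: int,
    charged: bool,
    vdw_bound: MeanSD,
    vdw_free: MeanSD,
    el_bound: MeanSD,
    el_free: MeanSD,
    delta_vdw: MeanSD,
    delta_el: MeanSD,
) -> InteractionEnergySummary:
    """Build a summary from printed (rounded) table values, kept verbatim.

    Printed difference columns may disagree with the difference of printed
    means by up to ~0.15 kcal/mol because of independent rounding; they are
    stored as printed rather than recomputed.
    """
    return InteractionEnergySummary(
        compound_id,
        charged,
        MeanSD(*vdw_bound),
        MeanSD(*vdw_free),
        MeanSD(*el_bound),
        MeanSD(*el_free),
        MeanSD(*delta_vdw),
        MeanSD(*delta_el),
    )


def group_sd_average(
    summaries: Sequence[InteractionEnergySummary],
    group: str,
    field: str,
) -> tuple[float, float]:
    """Mean fluctuation SD of a field over the charged or neutral compounds.

    Returns ``(rounded, unrounded)`` where the rounded value uses one decimal,
    the convention of the published fluctuation comparison (e.g. bound-state
    electrostatic SDs average 1.9 kcal/mol over the charged compounds).
    """
    if group not in ("charged", "neutral"):
        raise InvalidInputError(f"group must be 'charged' or 'neutral', got {group!r}")
    if field not in GROUP_FIELDS:
        raise InvalidInputError(f"field must be one of {GROUP_FIELDS}, got {field!r}")
    if not summaries:
        raise InvalidInputError("no summaries given")
    want = group == "charged"
    sds = [getattr(s, field).sd for s in summaries if s.charged == want]
    if not sds:
        raise InvalidInputError(f"no compounds in group {group!r}")
    unrounded = float(np.mean(sds))
    return round_half_away(unrounded, 1), unrounded


# ---------------------------------------------------------------------------
# Energy TSV dialect
#
# A file holds one or more sections.  Each section starts with a header line
#   # compound=<id> state=<bound|free> component=<vdw|el> interval_ps=<float>
# followed by one energy (kcal/mol) per line.  Energies are written in repr
# precision so the dialect round-trips bit-exactly.
# ---------------------------------------------------------------------------


def _parse_header(line: str, lineno: int) -> dict:
    fields = {}
    for token in line.lstrip("#").split():
        if "=" not in token:
            raise FormatError(f"line {lineno}: malformed header token {token!r}")
        k, v = token.split("=", 1)
        fields[k] = v
    for key in ("compound", "state", "component", "interval_ps"):
        if key not in fields:
            raise FormatError(f"line {lineno}: header missing field {key!r}")
    try:
        return {
            "compound_id": int(fields["compound"]),
            "state": fields["state"],
            "component": fields["component"],
            "sampling_interval_ps": float(fields["interval_ps"]),
        }
    except ValueError as exc:
        raise FormatError(f"line {lineno}: {exc}") from exc


def read_energy_tsv(path: str | Path) -> list[EnergyTimeSeries]:
    """Read all energy series from a file in the documented dialect."""
    path = Path(path)
    series: list[EnergyTimeSeries] = []
    header: dict | None = None
    values: list[float] = []
    seen: set[tuple] = set()

    def flush(lineno: int):
        nonlocal header, values
        if header is None:
            return
        if not values:
            raise FormatError(f"line {lineno}: section for compound {header['compound_id']} is empty")
        key = (header["compound_id"], header["state"], header["component"])
        if key in seen:
            raise FormatError(f"line {lineno}: duplicate series {key}")
        seen.add(key)
        series.append(EnergyTimeSeries(values=np.array(values), **header))
        header, values = None, []

    with path.open() as fh:
        lineno = 0
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                flush(lineno)
                header = _parse_header(line, lineno)
                continue
            if header is None:
                raise FormatError(f"line {lineno}: data before any section header")
            try:
                values.append(float(line))
            except ValueError:
                raise FormatError(
                    f"line {lineno}: non-numeric energy value {line!r}"
                ) from None
        flush(lineno + 1)
    if not series:
        raise FormatError(f"{path}: no energy series found")
    return series


def write_energy_tsv(path: str | Path, series: Iterable[EnergyTimeSeries]) -> None:
    """Write series in the dialect read back by :func:`read_energy_tsv`."""
    path = Path(path)
    with path.open("w") as fh:
        for s in series:
            fh.write(
                f"# compound={s.compound_id} state={s.state} "
                f"component={s.component} interval_ps={s.sampling_interval_ps!r}\n"
            )
            for v in s.values:
                fh.write(f"{float(v)!r}\n")
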