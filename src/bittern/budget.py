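"""Analytic deployment budget for the sensor-network recognizer.

Three small models answer three deployment questions:

* **How expensive is classification?** Per frame, scoring n classes of
  M full-covariance Gaussians in d dimensions costs n*M*d subtractions,
  n*M*(d^2 + d + 1) multiplications and n*M*((d-1)^2 + d) additions
  (|Sigma| and Sigma^-1 are precomputed, so only the Mahalanobis product,
  the exponential-argument scaling and the weighted sum remain at run
  time). Multiplying by the frame rate and the sensor count gives the
  sustained FLOPS the central node must deliver.

* **How many sensors fit in real time?** The feature pipeline's critical
  path takes a fixed number of clock cycles per frame; with a 15 ms hop
  (30 ms frames, 50% overlap) the node can interleave
  floor(hop / latency) independent audio streams.

* **Does the feature IP fit a given FPGA?** Required DSP slices, block
  RAMs, LUTs and flip-flops as a percentage of a device's capacity.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

_CATALOG_RESOURCE = "zynq7000.json"
_RESOURCE_FIELDS = ("dsp", "bram_blocks", "lut", "ff")


@dataclass(frozen=True)
class GMMCostSpec:
    """Problem size of the classifier: n classes, M mixtures, d dimensions."""

    n: int
    M: int
    d: int

    def __post_init__(self) -> None:
        if min(self.n, self.M, self.d) < 1:
            raise ValueError("n, M and d must all be >= 1")


@dataclass(frozen=True)
class ThroughputSpec:
    """Timing of the per-frame feature pipeline."""

    frame_ms: float = 30.0
    overlap: float = 0.5
    cycles_per_frame: int = 49156
    clock_hz: float = 100e6

    def __post_init__(self) -> None:
        if self.cycles_per_frame <= 0 or self.clock_hz <= 0:
            raise ValueError("cycles_per_frame and clock_hz must be positive")
        if not 0 <= self.overlap < 1:
            raise ValueError("overlap must be in [0, 1)")

    @property
    def hop_s(self) -> float:
        """Frame advance in seconds — the real-time deadline per stream."""
        return self.frame_ms / 1000.0 * (1.0 - self.overlap)

    @property
    def frame_latency_s(self) -> float:
        return self.cycles_per_frame / self.clock_hz


@dataclass(frozen=True)
class ResourceTable:
    """FPGA resource amounts: DSP slices, 36 Kb BRAM blocks, LUTs, FFs."""

    dsp: int
    bram_blocks: int
    lut: int
    ff: int

    def __post_init__(self) -> None:
        if min(self.dsp, self.bram_blocks, self.lut, self.ff) < 0:
            raise ValueError("resource counts must be non-negative")


def gmm_flop_count(spec: GMMCostSpec) -> dict[str, int]:
    """Floating-point operations to score one frame against every model."""
    nM = spec.n * spec.M
    d = spec.d
    subs = nM * d
    mults = nM * (d * d + d + 1)
    adds = nM * ((d - 1) * (d - 1) + d)
    return {"subtractions": subs, "multiplications": mults,
            "additions": adds, "total": subs + mults + adds}


def system_flops(per_frame_ops: float, hop_s: float, n_sensors: int) -> float:
    """Sustained operation rate: per-frame cost x sensors / frame period."""
    if hop_s <= 0:
        raise ValueError("hop_s must be positive")
    if n_sensors < 1:
        raise ValueError("need at least one sensor")
    return per_frame_ops * n_sensors / hop_s


def sensor_capacity(ts: ThroughputSpec) -> int:
    """Independent audio streams servable in real time: floor(hop/latency).

    A partial sensor is no sensor; capacity 0 means the pipeline cannot
    keep up with even a single stream.
    """
    capacity = math.floor(ts.hop_s / ts.frame_latency_s)
    if capacity == 0:
        import warnings
        warnings.warn(
            f"frame latency {ts.frame_latency_s * 1e6:.1f} us exceeds the "
            f"{ts.hop_s * 1e6:.0f} us hop: no stream can run in real time",
            stacklevel=2)
    return capacity


@dataclass(frozen=True)
class ResourceFit:
    device: str
    percent: dict[str, float]
    fits: bool


def resource_fit(required: ResourceTable, device: ResourceTable,
                 device_name: str = "") -> ResourceFit:
    """Required resources as a percentage of a device's capacity.

    Percentages are rounded half-even to 2 decimals; ``fits`` is true
    when every resource is at or under 100%.
    """
    percent = {}
    for fld in _RESOURCE_FIELDS:
        cap = getattr(device, fld)
        if cap <= 0:
            raise ValueError(f"{device_name or 'device'}: zero capacity for {fld}")
        percent[fld] = round(100.0 * getattr(required, fld) / cap, 2)
    fits = all(100.0 * getattr(required, f) / getattr(device, f) <= 100.0
               for f in _RESOURCE_FIELDS)
    return ResourceFit(device=device_name, percent=percent, fits=fits)


def _read_catalog(path: str | Path | None = None) -> dict:
    if path is not None:
        text = Path(path).read_text()
    else:
        text = (resources.files("bittern") / "data" / _CATALOG_RESOURCE).read_text()
    try:
        payload = json.loads(text)
        devices = payload["devices"]
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise ValueError(f"malformed device catalog: {exc}") from exc
    return payload


def load_device_catalog(path: str | Path | None = None) -> dict[str, ResourceTable]:
    """Device-name -> capacity map; defaults to the bundled Zynq-7000 table."""
    payload = _read_catalog(path)
    catalog = {}
    for name, caps in payload["devices"].items():
        try:
            catalog[name] = ResourceTable(**caps)
        except TypeError as exc:
            raise ValueError(f"malformed catalog entry {name!r}: {exc}") from exc
    return catalog


def feature_ip_requirements(path: str | Path | None = None
                            ) -> tuple[ResourceTable, ThroughputSpec]:
    """Packaged feature-IP resource totals and its per-frame timing."""
    payload = _read_catalog(path)
    ip = payload["feature_ip"]
    req = ResourceTable(**ip["total"])
    ts = ThroughputSpec(cycles_per_frame=ip["critical_path_cycles"],
                        clock_hz=ip["clock_hz"])
    return req, ts


@dataclass
class BudgetReport:
    """Everything the budget computes for one configuration."""

    cost: GMMCostSpec
    ops_per_frame: dict[str, int]
    hop_s: float
    n_sensors: int
    flops: float
    capacity: int
    fits: list[ResourceFit]

    def to_dict(self) -> dict:
        return {
            "classes": self.cost.n, "mixtures": self.cost.M,
            "dimensions": self.cost.d, "ops_per_frame": self.ops_per_frame,
            "hop_s": self.hop_s, "n_sensors": self.n_sensors,
            "system_flops": self.flops, "sensor_capacity": self.capacity,
            "device_fit": [
                {"device": f.device, "percent": f.percent, "fits": f.fits}
                for f in self.fits],
        }


def full_budget(n: int = 20, M: int = 32, d: int = 13, n_sensors: int = 30,
                frame_ms: float = 30.0, overlap: float = 0.5,
                cycles_per_frame: int | None = None,
                clock_hz: float | None = None,
                devices: list[str] | None = None,
                catalog_path: str | Path | None = None) -> BudgetReport:
    """Run the whole budget with the recognizer defaults."""
    cost = GMMCostSpec(n=n, M=M, d=d)
    ops = gmm_flop_count(cost)
    req, ts_default = feature_ip_requirements(catalog_path)
    ts = ThroughputSpec(
        frame_ms=frame_ms, overlap=overlap,
        cycles_per_frame=cycles_per_frame or ts_default.cycles_per_frame,
        clock_hz=clock_hz or ts_default.clock_hz)
    catalog = load_device_catalog(catalog_path)
    names = devices if devices else list(catalog)
    fits = [resource_fit(req, catalog[name], name) for name in names]
    return BudgetReport(
        cost=cost, ops_per_frame=ops, hop_s=ts.hop_s, n_sensors=n_sensors,
        flops=system_flops(ops["total"], ts.hop_s, n_sensors),
        capacity=sensor_capacity(ts), fits=fits)
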