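"""End-to-end EEG analysis: baseline, spikes, SWDs, rates, SWD spectrum."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .eeg_io import EEGRecording, EventTable
from .spectral import PSDResult, SpectralParams, swd_psd
from .spikes import DetectionParams, SpikeEvent, detect_spikes, spike_frequency
from .swd import SWDEvent, SWDParams, detect_swds, swd_statistics


@dataclass
class EEGAnalysis:
    """Joint result of spike detection, SWD clustering and SWD spectrum."""

    spikes: list[SpikeEvent]
    swds: list[SWDEvent]
    spikes_per_hour: float
    swds_per_hour: float
    mean_swd_length_s: float | None
    psd: PSDResult | None  # None when no SWDs were found

    def summary(self) -> str:
        lines = [
            "EEG epileptiform-activity analysis",
            "=" * 40,
            f"solitary spikes/h : {self.spikes_per_hour:.2f}",
            f"SWDs/h            : {self.swds_per_hour:.2f}",
        ]
        if self.mean_swd_length_s is not None:
            lines.append(f"mean SWD length   : {self.mean_swd_length_s:.3f} s")
        if self.psd is not None:
            lines.append(f"SWD spectral peak : {self.psd.peak_frequency:.1f} Hz")
        return "\n".join(lines)


def analyze_recording(
    recording: EEGRecording,
    artifacts: EventTable | None = None,
    detection: DetectionParams | None = None,
    swd_params: SWDParams | None = None,
    spectral: SpectralParams | None = None,
    channel: str | None = None,
) -> EEGAnalysis:
    """Run the full detection chain on one channel of a recording.

    Artifact intervals (if given) are excluded from baseline estimation and
    from all counts. The analyzed duration for the hourly rates is the
    recording length minus the artifact-covered time.
    """
    detection = detection or DetectionParams()
    swd_params = swd_params or SWDParams()
    spectral = spectral or SpectralParams()

    spikes = detect_spikes(recording, detection, artifacts, channel=channel)
    swds = detect_swds(spikes, swd_params)

    analyzed = recording.duration
    if artifacts is not None and len(artifacts):
        iv = artifacts.intervals()
        analyzed -= float((iv[:, 1] - iv[:, 0]).sum())
    analyzed = max(analyzed, 1e-9)

    sph = spike_frequency(spikes, swds, analyzed)
    swd_rate, mean_len, _ = swd_statistics(swds, analyzed)
    psd = swd_psd(recording, swds, spectral, channel=channel) if swds else None
    return EEGAnalysis(
        spikes=spikes,
        swds=swds,
        spikes_per_hour=sph,
        swds_per_hour=swd_rate,
        mean_swd_length_s=mean_len,
        psd=psd,
    )
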