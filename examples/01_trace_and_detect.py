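"""Generate a synthetic area trace with programmed collapses and detect them.

Builds one embryo whose cavity grows logistically between blastulation
onset (tSB) and full blastocyst formation (tB), programs one collapse in
each phase, and shows that the detector recovers start time, shrinkage and
recovery duration on the 10-minute frame grid.
"""

from blastotrace import CollapseSpec, SceneSpec, detect_collapses, make_area_trace

scene = SceneSpec(
    tSB_hpi=100.0,
    tB_hpi=110.0,
    end_hpi=140.0,
    collapses=[
        CollapseSpec(start_hpi=106.5, shrinkage_frac=0.24, recovery_duration_h=0.9),
        CollapseSpec(start_hpi=121.0, shrinkage_frac=0.30, recovery_duration_h=1.0),
    ],
)
trace, truth = make_area_trace(scene)
print(f"trace: {trace.n_frames} frames every {trace.frame_interval_min:.0f} min, "
      f"tSB={trace.tSB_hpi} tB={trace.tB_hpi} (hpi)")

events = detect_collapses(trace, min_drop=0.05)
for e, gt in zip(events, truth):
    print(
        f"{e.phase:>9}: start {e.start_hpi:6.1f} hpi  "
        f"shrinkage {100 * e.shrinkage:4.1f}% (programmed {100 * gt.shrinkage:4.1f}%)  "
        f"recovery {e.recovery_duration_h:.2f} h (programmed {gt.recovery_duration_h:.2f} h)"
    )
# Shrinkage is the fraction of the reference area lost at the minimum:
# before tB the reference is the pre-collapse cavity area, after tB the
# area inside the zona pellucida.  Recovery = time from the minimum back
# to 90% of the pre-collapse cavity area, quantised to the frame grid.
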