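"""Score drought events with the optimized and the equal-weight index.

Generates a TCI-dominated scene with five injected events (severities from
a deep drought to a no-drought control), calibrates the weights, and
compares the drought detection efficiency (DTE) of VHI_opt against the
equal-weight baseline VHI_ori on the same event catalog.
"""

from vhiopt import (
    compute_vhi, compute_vhi_opt, detection_efficiency, detection_scenario,
    generate_cubes, optimize_contribution, score_event,
)

scenario = detection_scenario(seed=7)
vci, tci, ref, truth = generate_cubes(scenario)

cmap = optimize_contribution(vci, tci, ref)
vhi_opt = compute_vhi_opt(vci, tci, cmap)
vhi_ori = compute_vhi(vci, tci, 0.5)

print("event        year  severity  frac_opt  frac_ori  score_opt  score_ori")
scores_opt, scores_ori = [], []
for ev, spec in zip(truth.events, scenario.events):
    so = score_event(vhi_opt, ev)
    sb = score_event(vhi_ori, ev)
    scores_opt.append(so)
    scores_ori.append(sb)
    print(f"{ev.event_id:<12s} {ev.year}  {spec.severity:8.1f}  {so.fraction:8.2f}  "
          f"{sb.fraction:8.2f}  {so.score:9.1f}  {sb.score:9.1f}")

dte_opt = detection_efficiency(scores_opt).dte
dte_ori = detection_efficiency(scores_ori).dte
print(f"\nDTE (VHI_opt): {dte_opt:.2f}%")
print(f"DTE (VHI_ori): {dte_ori:.2f}%")

# Each event's drought lives in the pixel's true moisture signal, so the
# calibrated index sees the full drop while the equal-weight index sees it
# attenuated: VHI_opt flags a larger pixel fraction and scores at least as
# high on every event.
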