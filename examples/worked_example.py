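"""Simulate one post-contact afforestation record and classify it.

Prints the record's class and its evidence bundle; this is the snippet
whose output appears in the README.
"""

import dataclasses

import forestsignal as fs

spec = dataclasses.replace(
    fs.scenario_library()["post_contact_afforestation"], seed=1
)
record = fs.simulate_pollen_record(spec)
stages = fs.prepare_pollen(record, fs.synthetic_pfg_map())
result = fs.classify_stages(stages)

post = result.post_evidence
print("record:", record.metadata.site_id)
print("class: ", result.vegetation_class.value)
print(
    f"post window {stages.windows.post_window}: proxy {post.proxy_direction.value} "
    f"(d-openness = {post.proxy_magnitude:+.3f}), trend {post.gam_direction.value}, "
    f"clear PFG change = {post.pfg_clear_change} (dAP = {post.pfg_delta_pp:+.1f} pp)"
)
print(f"GAM: k = {stages.fit.k}, edf = {stages.fit.edf:.2f}")
print(
    f"zones: {stages.zonation.n_zones}, boundaries (CE): "
    f"{[round(b) for b in stages.zonation.zone_boundaries]}"
)
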