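"""Worked ICC arithmetic on the default variance decomposition.

ICC = (s2_t + s2_j + s2_s) / (s2_t + s2_j + s2_s + s2_js): the share of a
species-by-stream combination's temporal variance that it shares with the
wider community.
"""

from streamsync import ScenarioConfig, plug_in_icc

cfg = ScenarioConfig()
print("species stream   s2_j  s2_s  s2_js   ICC")
for j, sp in enumerate(cfg.species):
    for s, st in enumerate(cfg.streams):
        icc = plug_in_icc(cfg.sigma2_t, cfg.sigma2_j[j], cfg.sigma2_s[s],
                          cfg.sigma2_js[j][s])
        print(f"{sp:7s} {st:7s} {cfg.sigma2_j[j]:5.2f} {cfg.sigma2_s[s]:5.2f} "
              f"{cfg.sigma2_js[j][s]:6.2f} {icc:6.2f}")
print(f"\n(overall temporal variance s2_t = {cfg.sigma2_t})")
# Creek chub in Indian Creek: (0.60+0.44+0.64)/(0.60+0.44+0.64+0.60) = 0.74.
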