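"""The economic KPI chain on one benchmark cohort row.

Takes the December 2023 cohort-6 means (86.5 lb milk at 4.32% fat,
3.34% protein) and walks the chain: energy-corrected milk, feed
efficiency against the reported 60.0 lb DMI, a standardized component
price, and income over feed cost.
"""

from herdbench import PriceConfig, ecm_lb, feed_efficiency, iofc_day, milk_price_cwt

milk, fat, protein, scc = 86.5, 4.32, 3.34, 145.0
dmi = 60.0

ecm = ecm_lb(milk, fat, protein)
fe = feed_efficiency(ecm, dmi)
cfg = PriceConfig()
price = milk_price_cwt(fat, protein, scc, cfg)
feed_cost = dmi * cfg.ration_price_lb_dm
iofc = iofc_day(milk, price, feed_cost)

print(f"ECM            {ecm:6.2f} lb/cow/day  (milk normalized to 3.5% fat / 3.2% protein)")
print(f"FE             {fe:6.2f}             (ECM per lb of dry matter eaten)")
print(f"milk price     {price:6.2f} $/cwt      (Class III base + component adjustments)")
print(f"feed cost      {feed_cost:6.2f} $/cow/day")
print(f"IOFC           {iofc:6.2f} $/cow/day  (milk income minus feed cost)")
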