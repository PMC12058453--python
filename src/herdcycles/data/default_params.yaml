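# Default tri-trophic model parameters.
# Units: Mg dry weight, km^2, years, individuals/km^2.
u0: 0.8      # vegetation regrowth rate
m: 100.0     # maximum vegetation coverage
a: 2.5       # herbivore foraging rate
b: 25.4      # herbivore half-saturation constant
xi: 0.27     # herbivore conversion efficiency
eta: 0.89    # herbivore ZPG consumption rate
c: 18.5      # predator foraging rate
d: 0.5       # predator half-saturation constant
chi: 0.114   # predator conversion efficiency
mu: 9.25     # predator ZPG consumption rate
s0: 0.3      # intrinsic rate of predator increase
kappa: 0.1   # maximum predator density
r0: 0.3      # intrinsic herbivore growth rate (used to derive xi)
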