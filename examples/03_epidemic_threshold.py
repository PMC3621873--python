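"""Vaccination thresholds and attack rates for an influenza-like disease.

For each basic reproduction number R0 the herd-immunity threshold is
1 - 1/R0; integrating the SIR model at coverages just below and above it
shows the epidemic switching between a major outbreak and a fizzle.
"""

from vaxgame import SIRParams, integrate_sir, vaccination_threshold

GAMMA = 0.312  # recovery rate per day (3.2-day infectious period)

print("R0     threshold   attack @ V=theta-0.10   attack @ V=theta+0.05")
for R0 in (1.2, 1.6, 2.0):
    theta = vaccination_threshold(R0)
    rates = []
    for V in (max(0.0, theta - 0.10), theta + 0.05):
        summary = integrate_sir(
            SIRParams(beta=R0 * GAMMA, gamma=GAMMA, N=1.0, V=V, I0=1e-4)
        )
        rates.append(summary.attack_rate)
    print(f"{R0:.1f}      {theta:.3f}          {rates[0]:.3f}"
          f"                   {rates[1]:.4f}")

print("\nAttack rate = fraction of the whole population ever infected;")
print("above the threshold only the seeded infections ever occur.")
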