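"""Free-energy cost of nitrate uptake as the environment is drawn down.

Evaluates Delta_rG = RT ln([n]_I/[n]_E) + zF*DeltaPsi for a monovalent
anion (z = -1) imported against a typical bacterial membrane potential,
across external nitrate concentrations spanning the nitracline.
"""

from picotrait.energetics import TransportContext, transport_free_energy

T = 298.15          # K
n_in = 100e-6       # 100 uM intracellular pool
delta_psi = -0.14   # V, inside-negative

print("external nitrate   Delta_rG (kJ/mol)")
for n_out_um in (10.0, 1.0, 0.1, 0.01):
    ctx = TransportContext(
        temperature=T, n_in=n_in, n_out=n_out_um * 1e-6,
        z=-1, delta_psi=delta_psi,
    )
    dg = transport_free_energy(ctx) / 1000.0
    print(f"  {n_out_um:7.2f} uM      {dg:8.2f}")
print("each 10-fold drawdown of external nitrate adds RT ln 10 "
      "(~5.7 kJ/mol) to the uptake cost; importing an anion against an "
      "inside-negative potential adds a further |z F DeltaPsi|")
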