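"""Physical constants and unit conversions, pinned to CODATA-2018.

All literals used for unit conversion live here; modules import these
names rather than repeating numbers.

Internal unit system
--------------------
length     Å
time       ps
energy     kcal/mol   (simulation forces)
charge     e
dipole     debye      (reported)
field      MV/m       (reported)
"""

#: Elementary charge [C] (exact, CODATA-2018).
ELEMENTARY_CHARGE_C = 1.602176634e-19

#: One debye [C·m].
DEBYE_CM = 3.33564e-30

#: Boltzmann constant [J/K] (exact, CODATA-2018).
BOLTZMANN_J_PER_K = 1.380649e-23

#: Boltzmann constant [kcal/mol/K] (via N_A = 6.02214076e23, 1 cal = 4.184 J).
BOLTZMANN_KCALMOL_PER_K = 1.987204259e-3

#: Dipole conversion: 1 e·Å in debye.  e·Å = 1.602176634e-29 C·m.
DEBYE_PER_E_ANGSTROM = ELEMENTARY_CHARGE_C * 1e-10 / DEBYE_CM  # 4.80321

#: Force conversion: 1 e·(MV/m) in N, and in pN.
NEWTON_PER_E_MVM = ELEMENTARY_CHARGE_C * 1e6
PN_PER_E_MVM = NEWTON_PER_E_MVM * 1e12  # 0.160218 pN

#: Force conversion for the simulator: 1 e·(MV/m) in kcal/mol/Å.
#: e·V/Å = 23.0605 kcal/mol/Å; 1 MV/m = 1e-4 V/Å.
KCALMOL_PER_ANGSTROM_PER_E_MVM = 23.060548 * 1e-4

#: Area: Å² per nm².
A2_PER_NM2 = 100.0

#: Default temperature for kT reporting [K].
ROOM_TEMPERATURE_K = 296.0
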