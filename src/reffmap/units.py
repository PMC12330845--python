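"""Internal unit system.

All quantities are carried in a single consistent system:

* time in ms, length in um, diffusivity in um^2/ms
* b-value in ms/um^2
* gradient amplitude in mT/m (converted internally where needed)

``GAMMA`` is the proton gyromagnetic ratio expressed so that
``GAMMA * g * delta`` (g in mT/m, delta in ms) is a wavenumber in rad/um,
and hence ``(GAMMA * g * delta)**2 * (Delta - delta/3)`` is a b-value in
ms/um^2.
"""

# 2.6752218744e8 rad s^-1 T^-1, rescaled to rad ms^-1 (mT/m)^-1 um^-1
GAMMA: float = 2.6752218744e-4

# Same constant in rad ms^-1 mT^-1 (per unit field rather than per gradient)
GAMMA_PER_MT: float = 267.52218744
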