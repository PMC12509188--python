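# Instrument parameter set of the modelled transmission O-PTIR microscope.
# Units: lengths um, powers mW, frequencies kHz, angles degrees, SI otherwise.

[probe_beam]
wavelength_um = 0.633
waist_um = 0.53
medium_index = 1.0003

[pump_beam]
wavelength_um = 6.895     # 1450 cm^-1 band of polystyrene
waist_um = 5.0
medium_index = 1.0003

[pump_drive]
average_power_mW = 6.6
duty_cycle = 0.025
modulation_frequency_kHz = 50.0

[medium]                   # dry air at 294 K
thermal_conductivity = 0.0262          # W m^-1 K^-1
specific_heat_capacity = 1006.0        # J kg^-1 K^-1
density = 1.204                        # kg m^-3
refractive_index = 1.0003
thermo_optic_coefficient = -9e-7       # K^-1 at 633 nm

[absorber]                 # 500 nm polystyrene bead
cross_section_um2 = 0.065  # expected sigma_abs at 1450 cm^-1
radius_um = 0.25

[detection]                # reflective (Schwarzschild) collection objective
theta_min_deg = 21.0
theta_max_deg = 30.0       # = arcsin(NA/n0) for NA 0.5 in air

[optics]                   # objectives used for the optical PSF calculations
raman_na = 0.55            # single-objective reflection confocal arm
optir_na = 0.5             # visible objective and reflective objective
optir_collection_theta_min_deg = 21.0  # central beam stop of the RO
apodization = "uniform"
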