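	IS257-2	IS257-1	IS257-3	IS431L	IS257R2	IS257R1	IS431mec	IS431R
IS257-2	100.00	96.55	97.04	96.05	96.05	95.56	96.05	96.55
IS257-1	96.55	100.00	98.66	98.21	98.66	98.21	98.66	99.10
IS257-3	97.04	98.66	100.00	98.66	99.10	98.66	99.10	99.10
IS431L	96.05	98.21	98.66	100.00	98.66	98.21	98.66	99.55
IS257R2	96.05	98.66	99.10	98.66	100.00	99.55	99.10	98.66
IS257R1	95.56	98.21	98.66	98.21	99.55	100.00	98.55	99.10
IS431mec	96.05	98.66	99.10	98.66	99.10	98.55	100.00	99.10
IS431R	96.55	99.10	99.10	99.55	98.66	99.10	99.10	100.00
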