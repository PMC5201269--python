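gene_id	family
hsp-60	Hsp60/10
hsp-10	Hsp60/10
cct-1	Hsp60/10
cct-2	Hsp60/10
cct-3	Hsp60/10
cct-4	Hsp60/10
cct-5	Hsp60/10
cct-6	Hsp60/10
cct-7	Hsp60/10
cct-8	Hsp60/10
hsp-1	Hsp70
hsp-3	Hsp70
hsp-4	Hsp70
hsp-6	Hsp70
hsp-70	Hsp70
f44e5.4	Hsp70
f44e5.5	Hsp70
c12c8.1	Hsp70
f11f1.1	Hsp70
stc-1	Hsp70
t14g8.3	Hsp70
c30c11.4	Hsp70
hsp-110	Hsp70
dnj-1	Hsp40/NEF
dnj-2	Hsp40/NEF
dnj-3	Hsp40/NEF
dnj-4	Hsp40/NEF
dnj-5	Hsp40/NEF
dnj-6	Hsp40/NEF
dnj-7	Hsp40/NEF
dnj-8	Hsp40/NEF
dnj-9	Hsp40/NEF
dnj-10	Hsp40/NEF
dnj-11	Hsp40/NEF
dnj-12	Hsp40/NEF
dnj-13	Hsp40/NEF
dnj-14	Hsp40/NEF
dnj-15	Hsp40/NEF
dnj-16	Hsp40/NEF
dnj-17	Hsp40/NEF
dnj-18	Hsp40/NEF
dnj-19	Hsp40/NEF
dnj-20	Hsp40/NEF
dnj-21	Hsp40/NEF
dnj-22	Hsp40/NEF
dnj-23	Hsp40/NEF
dnj-24	Hsp40/NEF
dnj-25	Hsp40/NEF
dnj-26	Hsp40/NEF
dnj-27	Hsp40/NEF
dnj-28	Hsp40/NEF
dnj-29	Hsp40/NEF
dnj-30	Hsp40/NEF
rme-8	Hsp40/NEF
unc-23	Hsp40/NEF
t05c3.5	Hsp40/NEF
y73b6bl.12	Hsp40/NEF
f39b2.10	Hsp40/NEF
c08h9.14	Hsp40/NEF
daf-21	Hsp90/cochaperone
sti-1	Hsp90/cochaperone
c01g10.8	Hsp90/cochaperone
cdc-37	Hsp90/cochaperone
pph-5	Hsp90/cochaperone
fkb-6	Hsp90/cochaperone
unc-45	Hsp90/cochaperone
chn-1	Hsp90/cochaperone
r05f9.10	Hsp90/cochaperone
sgt-1	Hsp90/cochaperone
tah-1	Hsp90/cochaperone
ppt-1	Hsp90/cochaperone
aip-1	Hsp90/cochaperone
hsp-12.1	sHsp
hsp-12.2	sHsp
hsp-12.3	sHsp
hsp-12.6	sHsp
hsp-16.1	sHsp
hsp-16.2	sHsp
hsp-16.11	sHsp
hsp-16.41	sHsp
hsp-16.48	sHsp
hsp-16.49	sHsp
hsp-17	sHsp
hsp-25	sHsp
hsp-43	sHsp
sip-1	sHsp
f08h9.3	sHsp
f08h9.4	sHsp
pfd-1	other
pfd-2	other
pfd-3	other
pfd-4	other
pfd-5	other
pfd-6	other
nud-1	other
c17g10.2	other
b0035.14	other
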