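# raschcat item bank v1
# 37-item hospital job-satisfaction questionnaire, 1-4 Likert responses
# (worse, bad, good, excellent), stored internally as categories 0-3.
# Difficulties in logits from the 2008 calibration; misfit rows carry no
# estimates and are excluded from adaptive administration.
# thresholds: -4.16,-1.50,2.66
item_id,label,difficulty,se,infit,outfit,status
1,Working environment and necessary equipment are,,,,,misfit
2,Feelings regarding the office and staff lounge are,,,,,misfit
3,Parking lots and vehicular traffic indications are,,,,,misfit
4,Meals provided to employees by hospital are,,,,,misfit
5,Hospital's disaster prevention ability is,,,,,misfit
6,Overall feeling of the current work environment is,,,,,misfit
7,Hospital benefits and salary provided to employees are,,,,,misfit
8,Salary and wage levels compared with other hospitals are,0.47,0.17,1.12,1.14,calibrated
9,"The performance appraisal system is open, fair and reasonable",,,,,misfit
10,My objective is closely consistent with hospital goals,0.5,0.17,1.15,1.09,calibrated
11,The hospital message delivery design works well for workers,2.73,0.13,1.12,0.97,calibrated
12,The Plan-Do-Check-Action and review measures are,-0.96,0.18,1.03,1.03,calibrated
13,The hospital work environment compared to others is,0.02,0.18,0.68,0.44,calibrated
14,Colleagues can cooperate with each other to achieve goals,1.18,0.16,0.93,0.95,calibrated
15,Interpersonal relationships with colleagues are harmonious,1.75,0.14,0.9,1,calibrated
16,My boss can give clear instructions to designate tasks,1.03,0.16,0.93,0.91,calibrated
17,My boss often makes appropriate decisions,-0.46,0.18,1.08,1.13,calibrated
18,My boss fully shoulders and assumes accountability,-0.11,0.18,1.11,1.22,calibrated
19,Communication and interaction with my boss is,-0.37,0.18,0.71,0.56,calibrated
20,"Overall, my boss performance can be scored as",-0.87,0.18,0.95,0.91,calibrated
21,Opportunities to exchange and share experiences with colleagues are,,,,,misfit
22,Opportunities to cooperate and communicate with other departments are,,,,,misfit
23,I often work together with colleagues to achieve objectives,-1.03,0.17,1.11,1.16,calibrated
24,Harmonious relations with members of other departments are,-0.46,0.18,0.86,0.83,calibrated
25,Opportunities to interact with members of other departments are,-0.49,0.18,1.05,0.97,calibrated
26,I can fully extend my professional competence and talent,-0.65,0.18,0.82,0.78,calibrated
27,Many learning and growth opportunities are available for me,-0.59,0.18,0.97,0.96,calibrated
28,My job is challenging,-0.24,0.18,0.85,0.84,calibrated
29,My job provides a sense of identity and accomplishment,0.17,0.18,1.25,1.4,calibrated
30,My hospital provides necessary on-the-job training courses,0.23,0.17,1.09,1.05,calibrated
31,Workload and working hours are well allocated,-0.14,0.18,0.99,1.01,calibrated
32,"I can engage in my work, career planning and future vision",-0.52,0.18,0.95,1,calibrated
33,I am always able to maintain a happy mood at work,-0.68,0.18,1.08,1.04,calibrated
34,My job burdens do not interfere with my family life,-0.49,0.18,0.94,0.86,calibrated
35,I can afford my living expenses with income from my job,,,,,misfit
36,This satisfaction survey can be expected to improve the workplace,,,,,misfit
37,I would recommend the hospital if my relatives needed treatment,,,,,misfit
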