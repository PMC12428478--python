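code,name,pub_date
P1,Outline of the National Health Care Service System Plan (2015-2020),2015.03.06
P2,Guidance Opinions on Promoting the Integration of Medical and Health Care Services with Older Adult Care Services,2015.11.18
P3,Outline of the Strategic Plan for the Development of Traditional Chinese Medicine (2016-2030),2016.02.22
P4,Division of Responsibilities for Key Tasks in Integrating Medical Care and Older Adult Care,2016.04.01
P5,Division of Responsibilities for Key Tasks in Integrating Medical Care and Older Adult Care (Civil Affairs),2016.04.07
P6,13th Five-Year Plan for the Development of Civil Affairs,2016.06.24
P7,'Healthy China 2030' Planning Outline,2016.10.25
P8,Opinions on Comprehensively Opening Up the Older Adult Care Service Market and Improving the Quality of Older Adult Care Services,2016.12.07
P9,13th Five-Year Plan for the Development of the Older Adult Care Service and the Construction of the Older Adult Care System,2017.02.28
P10,Opinions on Promoting the Development of Older Adult Care Services,2019.03.29
P11,Notice on Doing a Good Job in the Approval and Registration of Medical and Nursing Care Institutions,2019.05.27
P12,Several Opinions on Deepening the Development of Medical Care and Older Adult Care Integration,2019.10.23
P13,Service Guidelines for Medical and Older Adult Care Integration Institutions (Trial),2019.12.23
P14,Management Guidelines for Medical and Older Adult Care Integration Institutions (Trial Version),2020.02.17
P15,Selection of the First Batch of Pilot Institutions for Remote Collaborative Services Combining Medical Care and Older Adult Health Care,2020.08.28
P16,"Management Guidelines for Medical and Older Adult Care Integration Institutions (Trial Version, reissue)",2020.09.27
P17,Opinion on Promoting the Development of Home-Based and Community-Based Older Adult Care Services by Property Service Enterprises,2020.11.24
P18,Notice on Launching a Quality Improvement Campaign for Medical and Nursing Care Institutions,2020.12.03
P19,Opinions on Promoting the Healthy Development of Older Adult Care and Childcare Services,2020.12.14
P20,Action Plan for the Development of the Smart Health and Aging Industry (2021-2025),2021.10.20
P21,Opinions on Strengthening Aging Work in the New Era,2021.11.18
P22,14th Five-Year Plan for the Development of the National Aging Cause and the Older Adult Care Service System,2021.12.30
P23,Notice on Launching an Initiative to Enhance Community Medical and Older Adult Care Integration Capabilities,2022.03.23
P24,Guiding Opinions on Further Promoting the Development of Medical Care and Older Adult Care Integration,2022.07.18
P25,Notice on Promoting Typical Experiences from Pilot Programs Combining Medical Care and Older Adult Care,2023.03.14
P26,Guidelines for Home-based and Community-based Medical and Nursing Care Services (Trial Version),2023.11.01
P27,Guiding Opinions on Promoting High-Quality Development of Medical and Older Adult Care Integration Services,2024.12.12
P28,Opinions on Deepening the Reform and Development of Older Adult Care Services,2024.12.30
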